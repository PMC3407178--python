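Real wwPDB entries used by the worked-example acceptance tests
(1a2w.pdb, 1rbb.pdb, 3gax.pdb, 1g96.pdb). They are not distributed with
the package; on a machine with network access run:

    python -c "from hide.structure_io import fetch_pdb
    for pdb_id in ('1a2w', '1rbb', '3gax', '1g96'):
        fetch_pdb(pdb_id, 'tests/data/rcsb')"
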