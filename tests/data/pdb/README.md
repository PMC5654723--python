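# Crystal-structure inputs (not redistributable)

The acceptance checks against published crystal-structure numbers need the
PDB entries for yeast PDI (2B5E) and human PDI in its reduced (4EKZ) and
oxidized (4EL1) forms.  Fetch them once into this directory:

    curl -o tests/data/pdb/2b5e.pdb https://files.rcsb.org/download/2B5E.pdb
    curl -o tests/data/pdb/4ekz.pdb https://files.rcsb.org/download/4EKZ.pdb
    curl -o tests/data/pdb/4el1.pdb https://files.rcsb.org/download/4EL1.pdb

Without these files the corresponding tests in `tests/test_acceptance.py`
fail with the same instruction; every synthetic-structure check runs with
no downloads.
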