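# Reference data

`s4_matrices/` is a placeholder for plain-text transcriptions of the
association matrices deposited with the original captive-elk density
experiment (available only as a PDF supplement, so not bundled here).
If you transcribe them, store one TSV per network named

    <sex>_<low|medium|high>_<replicate>.tsv      e.g. female_low_1.tsv

in the format written by `proxnet.association.write_matrix_tsv`: a header
row and leading column of collar ids, tab-separated weights.  The two
reference-reproduction tests in `tests/test_acceptance.py` consume these
files and fail with an explanatory message while they are absent.  All
other tests and examples generate their inputs synthetically.
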