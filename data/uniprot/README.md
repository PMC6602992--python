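# UniProt reference sequences (not bundled)

The comparison of computed mature MW / pI values against the published
tobacco LHC table requires the canonical UniProt sequences and their
annotated chloroplast transit-peptide spans.  Sequence data is not
redistributed with this repository; fetch it once (network required):

    python scripts/fetch_uniprot.py

This writes `tobacco_lhc.fasta` into this directory with
`[transit=1..N]` header tags.  The lhcb3 entry (A0A076L1Y1) carries no
UniProt transit annotation; its cleavage site must be supplied manually
via a sidecar TSV (`identifier<TAB>transit_end`) if mature-protein
numbers are wanted for it.

Tests that need this file fail with a pointer here when it is absent.
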