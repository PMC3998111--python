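# Published network tables

Place the deposited whole-respiratory and therapeutic network edge tables
here, converted to the package's triple TSV dialect (columns `node_a`,
`node_b`, `kind_a`, `kind_b`, `raw_types`, `modifications`):

- `whole_triples.tsv` — the whole respiratory network (1830 nodes, 17275 links)
- `therapeutic_triples.tsv` — the therapeutic network (1193 nodes, 10679 links)

The reproduction tests in `tests/test_acceptance.py` read these files and
fail until they are provided; they are not shipped with the repository.
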