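# Curated MBC map drop-in

The curated metastatic-breast-cancer disease map (312-species CellDesigner
SBML and 340-node CSV edge table) is distributed with the original study
and is not redistributed here.  To run the analyses and acceptance tests
that depend on it, place the files in this directory as:

- `MBC_map.xml` — the CellDesigner SBML export
- `MBC_map.csv` — the signed edge table (columns: source, sign, target)

`analysis/01_build_map.py` and `analysis/04_topology_hubs.py` pick them up
automatically, as do the acceptance tests in
`tests/test_acceptance.py` (which fail with a pointer to this file when
the map is absent).
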