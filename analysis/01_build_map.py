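"""Load the EMT-core regulatory map, validate it, and take its census.

If the curated metastatic-breast-cancer map files are available under
``data/external/mbc/`` (MBC_map.xml / MBC_map.csv), their censuses are
reported as well; otherwise the analysis proceeds on the packaged fixture
alone.  Writes results/map_summary.json and results/emt_core_edges.csv.
"""

import json
from pathlib import Path

from emtmap import read_celldesigner_sbml, read_edge_table, summarize_map, validate_map, write_edge_table
from emtmap.synthetic import emt_core_fixture

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
EXTERNAL = ROOT / "data" / "external" / "mbc"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    summaries = {}

    fixture = emt_core_fixture()
    issues = validate_map(fixture)
    summary = summarize_map(fixture)
    summaries["emt_core_fixture"] = json.loads(summary.to_json())
    print(f"EMT-core fixture: {summary.n_species} species, {summary.n_interactions} interactions, "
          f"{len(issues)} validation issue(s)")
    print("  species by kind:", {k: v for k, v in summary.species_by_kind.items() if v})
    write_edge_table(fixture, RESULTS / "emt_core_edges.csv")

    for name, path, reader in (
        ("curated_sbml", EXTERNAL / "MBC_map.xml", read_celldesigner_sbml),
        ("curated_csv", EXTERNAL / "MBC_map.csv", read_edge_table),
    ):
        if path.exists():
            m = reader(path)
            s = summarize_map(m)
            summaries[name] = json.loads(s.to_json())
            print(f"{name}: {s.n_species} species, {s.n_interactions} interactions")
        else:
            print(f"{name}: not present at {path} (skipped)")

    (RESULTS / "map_summary.json").write_text(json.dumps(summaries, indent=2) + "\n")
    print(f"wrote {RESULTS / 'map_summary.json'}")


if __name__ == "__main__":
    main()
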