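"""Recompute every percentage in the emulated study's cohort-flow summary
from its raw counts (exclusions, retention, trauma type, predictive-edge
sign split)."""

from pathlib import Path

from traumacpm import report

RESULTS = Path("results")


def main() -> None:
    table = report.study_flow_table()
    table.to_csv(RESULTS / "study_flow.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
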