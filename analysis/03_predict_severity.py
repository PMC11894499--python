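"""Predict CAPS-5 total severity at 1, 6 and 14 months with repeated
cross-validated CPM, plus permutation significance for each target.

Follow-up targets additionally control for baseline (1-month) severity, so
their scores reflect prediction of symptom change beyond initial severity.
"""

from pathlib import Path

import pandas as pd

from traumacpm import cpm, inference, io, pipeline

SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")
SEED = 7
REPEATS, N_PERM, PERM_REPEATS = 50, 200, 5


def main() -> None:
    ids, edges = io.read_edges_table(SCRATCH / "edges.csv")
    phen = io.read_phenotype(SCRATCH / "phenotype.csv")

    rows = []
    for target in ("1m", "6m", "14m"):
        kept, e, y, X = pipeline.assemble(edges, phen, target)
        run = cpm.run_cv(e, y, X, repeats=REPEATS, seed=SEED)
        perm = inference.permutation_test(
            e, y, X, n_perm=N_PERM, perm_repeats=PERM_REPEATS, seed=SEED,
            observed_run=run)
        rows.append({"target": target, "n_subjects": len(kept),
                     "n_covariates": X.shape[1],
                     "median_rho": round(cpm.score(run), 3),
                     "perm_p": round(perm.p_one_tailed, 4)})
        print(f"{target}: n={len(kept)}  median rho={rows[-1]['median_rho']}"
              f"  one-tailed p={rows[-1]['perm_p']}")

    pd.DataFrame(rows).to_csv(RESULTS / "prediction_summary.csv", index=False)


if __name__ == "__main__":
    main()
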