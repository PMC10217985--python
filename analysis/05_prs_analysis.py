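"""Polygenic risk score computation and rank-based outcome comparison.

Scores every subject with the normalized β-weighted genotype score and
compares score distributions between subjects with and without each
severe outcome, per therapy stratum (Mann-Whitney U), mirroring the
outcome × stratum p-value matrix layout.
"""

import importlib.util
from pathlib import Path

from sscpgx import apply_ld_collapse, cohort_prs, prs_outcome_matrix
from sscpgx.io import read_weights, write_table
from sscpgx.prs import comparison_frame, comparison_long_frame

_spec = importlib.util.spec_from_file_location(
    "cohort_loader", Path(__file__).with_name("02_cohort_summary.py")
)
_loader = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_loader)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort, ld_pairs = _loader.load_cohort()
    for a, b in ld_pairs:
        cohort, _ = apply_ld_collapse(cohort, a, b)
    weights = read_weights(ROOT / "cohort" / "weights.tsv")
    scores = cohort_prs(cohort, weights)
    write_table(scores, ROOT / "prs_scores.tsv")
    comparisons = prs_outcome_matrix(cohort, weights)
    write_table(comparison_long_frame(comparisons), ROOT / "prs_comparisons.tsv")
    matrix = comparison_frame(comparisons)
    write_table(matrix, ROOT / "prs_matrix.tsv", index=True)
    print(f"scores: n={len(scores)}, mean={scores['score'].mean():.3f}, "
          f"range [{scores['score'].min():.3f}, {scores['score'].max():.3f}]")
    print("\nMann-Whitney p-values (rows: outcomes, columns: strata):")
    print(matrix.round(4).to_string())
    nan_cells = [
        (c.outcome, c.stratum) for c in comparisons
        if c.n_with == 0 or c.n_without == 0
    ]
    if nan_cells:
        print(f"\nNaN cells (empty comparison group): {nan_cells}")


if __name__ == "__main__":
    main()
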