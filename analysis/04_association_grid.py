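"""Dominant-model stratified association grid with age/sex adjustment.

After collapsing the perfect-LD pair, fits the unadjusted and adjusted
logistic model for every marker × outcome × stratum cell and writes the
full grid plus the forest-plot export.
"""

import importlib.util
from pathlib import Path

from sscpgx import apply_ld_collapse, forest_plot_data, results_to_frame, run_association_grid
from sscpgx.io import write_table

_spec = importlib.util.spec_from_file_location(
    "cohort_loader", Path(__file__).with_name("02_cohort_summary.py")
)
_loader = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_loader)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort, ld_pairs = _loader.load_cohort()
    for a, b in ld_pairs:
        cohort, res = apply_ld_collapse(cohort, a, b)
        if res.marker_name:
            print(f"collapsed {a}+{b} -> {res.marker_name}")
    results = run_association_grid(cohort)
    df = results_to_frame(results)
    write_table(df, ROOT / "association.tsv")
    write_table(forest_plot_data(results), ROOT / "forest_data.tsv")
    est = df[df["estimable"]]
    sig = est[est["p_value"] < 0.05]
    print(f"grid: {len(df)} cells ({len(est)} estimable, "
          f"{len(df) - len(est)} flagged non-estimable)")
    print(f"{len(sig)} cells significant at alpha=0.05 (no multiplicity "
          f"correction; supplementary BH column in association.tsv):")
    for _, r in sig.iterrows():
        tag = "adj" if r["adjusted"] else "unadj"
        print(f"  {r['marker']:>15} x {r['outcome']:<21} x {r['stratum']:<6} "
              f"({tag}): OR {r['odds_ratio']:.2f} "
              f"[{r['ci_low']:.2f}-{r['ci_high']:.2f}], p={r['p_value']:.3f}")


if __name__ == "__main__":
    main()
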