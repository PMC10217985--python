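"""Genotype QC: allele frequencies, Hardy-Weinberg tests, LD collapse.

Computes per-variant allele frequencies and the HWE chi-square test,
then checks the configured perfect-LD pair and reports whether it
collapses into a single haplotype marker.
"""

import importlib.util
from pathlib import Path

import pandas as pd

from sscpgx import allele_frequencies, collapse_perfect_ld, hwe_chi_square
from sscpgx.io import write_table

_spec = importlib.util.spec_from_file_location(
    "cohort_loader", Path(__file__).with_name("02_cohort_summary.py")
)
_loader = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_loader)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort, ld_pairs = _loader.load_cohort()
    rows = []
    for rsid in cohort.rsids:
        freq = allele_frequencies(cohort, rsid)
        hwe = hwe_chi_square(freq.counts)
        rows.append(
            {"rsid": rsid, "n_called": freq.counts.total,
             "minor_freq": freq.minor_freq, "hwe_chi2": hwe.chi2, "hwe_p": hwe.p}
        )
    df = pd.DataFrame(rows)
    write_table(df, ROOT / "hwe.tsv")
    print(df.round(4).to_string(index=False))
    n_fail = int((df["hwe_p"] < 0.05).sum())
    print(f"\n{n_fail} of {len(df)} variants deviate from HWE at alpha=0.05")
    for a, b in ld_pairs:
        res = collapse_perfect_ld(cohort, a, b)
        verdict = (
            f"perfectly concordant over {res.n_overlap} subjects -> "
            f"merged as {res.marker_name}"
            if res.concordant and res.marker_name
            else f"not collapsed ({res.note})"
        )
        print(f"LD pair ({a}, {b}): {verdict}")


if __name__ == "__main__":
    main()
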