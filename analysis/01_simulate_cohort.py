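"""Generate the study-like synthetic cohort and write it as fixture files.

Simulates 102 subjects with the default study-like configuration (four
pharmacovariants, TPMT pair in perfect LD, ~85% women, four therapy
arms, five outcomes with planted genotype effects) and writes VCF +
phenotype + panel files under results/cohort/.
"""

from pathlib import Path

from sscpgx import generate_cohort, study_like_config, write_fixture
from sscpgx.io import write_weights
from sscpgx.synthetic_data import example_weights

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    config = study_like_config(seed=SEED)
    cohort, truth = generate_cohort(config)
    paths = write_fixture(cohort, OUT, truth)
    write_weights(example_weights(), OUT / "weights.tsv")
    print(f"simulated cohort: n={cohort.n_subjects}, panel={cohort.rsids}")
    print(f"realized minor-allele freqs: "
          f"{ {k: round(v, 4) for k, v in truth.realized_minor_freqs.items()} }")
    print(f"realized outcome prevalences: "
          f"{ {k: round(v, 3) for k, v in truth.realized_prevalences.items()} }")
    print(f"wrote: {', '.join(str(p) for p in paths.values())}")


if __name__ == "__main__":
    main()
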