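"""Cohort description tables: train/test comparability and the sex gap.

Recomputes the published cohort statistics from their printed group
summaries (Cohen's d for strength by sex, the age t-test, the sex
chi-square), then reproduces the same tables on a generated cohort with an
unrelated-family test split.  Writes results/cohort_table.tsv and
results/strength_by_sex.tsv.
"""

from pathlib import Path

import pandas as pd

from neuroconfound import (
    GeneratorConfig,
    GroupSummary,
    chi_square_2x2,
    cohens_d,
    family_split,
    generate_cohort,
    two_sample_t_summary,
)
from neuroconfound.cohort_stats import cohort_comparison_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def published_statistics() -> None:
    d_tr = cohens_d(GroupSummary(525, 109.1, 6.0), GroupSummary(445, 125.5, 9.1))
    d_te = cohens_d(GroupSummary(38, 109.0, 5.2), GroupSummary(37, 126.1, 6.6))
    t, _, p_t = two_sample_t_summary(
        GroupSummary(970, 28.8, 3.7), GroupSummary(75, 28.5, 3.7)
    )
    x2, p_x = chi_square_2x2([[525, 445], [38, 37]])
    print("from the published group summaries:")
    print(f"  strength Cohen's d: training {d_tr:.1f}, testing {d_te:.1f}")
    print(f"  age train-vs-test t = {t:.3f} (p = {p_t:.3f})")
    print(f"  sex train-vs-test X2 = {x2:.3f} (p = {p_x:.3f})")


def synthetic_tables() -> None:
    cohort = generate_cohort(
        GeneratorConfig(n_subjects=1045, with_timeseries=False, seed=30)
    )
    train, test = family_split(cohort.subjects, 75, seed=31)
    table = cohort_comparison_table(cohort.subjects, train, test)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "cohort_table.tsv", sep="\t", index=False)
    print("\nsynthetic cohort (n=1045, 75 unrelated test subjects):")
    print(table.round(3).to_string(index=False))

    rows = []
    for label, mask in (("train", train), ("test", test)):
        sub = cohort.subjects.loc[mask]
        f = GroupSummary.from_values(sub.loc[sub.sex == "F", "strength"])
        m = GroupSummary.from_values(sub.loc[sub.sex == "M", "strength"])
        rows.append(
            {
                "split": label,
                "female": f"{f.mean:.1f} ± {f.sd:.1f}",
                "male": f"{m.mean:.1f} ± {m.sd:.1f}",
                "cohens_d": round(cohens_d(f, m), 1),
            }
        )
    by_sex = pd.DataFrame(rows)
    by_sex.to_csv(RESULTS / "strength_by_sex.tsv", sep="\t", index=False)
    print("\nstrength by sex (synthetic):")
    print(by_sex.to_string(index=False))


def main() -> None:
    published_statistics()
    synthetic_tables()


if __name__ == "__main__":
    main()
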