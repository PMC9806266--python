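"""Strength prediction with and without sex correction.

The headline contrast: on confounded synthetic cohorts (n=600 train, 75
unrelated test subjects), an l2 pipeline predicts the strength score well —
until features and target are demeaned by sex with training means, after
which held-out R^2 collapses toward zero.  Five seeded cohorts; writes
results/strength_prediction.tsv.
"""

from pathlib import Path

import pandas as pd

from neuroconfound.experiment import confound_collapse_run

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEEDS = range(5)


def main() -> None:
    rows = []
    for seed in SEEDS:
        r = confound_collapse_run(seed)
        rows.append(
            {
                "seed": seed,
                "r2_uncorrected": r["r2_uncorrected"],
                "r2_sex_corrected": r["r2_sex_corrected"],
            }
        )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "strength_prediction.tsv", sep="\t", index=False)
    print(df.round(3).to_string(index=False))
    print(
        f"\nmean held-out R^2: uncorrected {df.r2_uncorrected.mean():.3f}, "
        f"sex-corrected {df.r2_sex_corrected.mean():.3f}"
    )
    print(
        "sex demeaning removes nearly all apparent predictive power: the "
        "uncorrected model was largely decoding sex, not strength."
    )


if __name__ == "__main__":
    main()
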