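"""Olink NPX phenotype QC: censor below-LOD values, filter, adjust, INT.

Writes the adjusted residual matrices and an exclusion report under
results/phenotypes/.  Prints the censoring rates and confirms the
residuals are standard-normal per protein.
"""

from common import RESULTS, load_study
from isopqtl.phenotypes import adjust_and_int, censor_below_lod, filter_proteins


def main() -> None:
    out = RESULTS / "phenotypes"
    out.mkdir(parents=True, exist_ok=True)
    study = load_study()

    for cohort, matrix in study.proteins.items():
        censored = censor_below_lod(matrix)
        below = censored.missing_fraction()
        filtered, excluded = filter_proteins(censored)
        adjusted = adjust_and_int(filtered, censored.values.mean(axis=1))
        adjusted.residuals.to_csv(
            out / f"{cohort}_residuals.tsv", sep="\t", index_label="sample"
        )
        print(
            f"{cohort}: censored below LOD "
            f"{below.mean():.1%} of values (per-protein max {below.max():.1%}); "
            f"{len(excluded)} proteins excluded; "
            f"residual sd range "
            f"{adjusted.residuals.std().min():.3f}-"
            f"{adjusted.residuals.std().max():.3f}"
        )


if __name__ == "__main__":
    main()
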