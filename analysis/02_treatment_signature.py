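"""Month-3 vs baseline anti-TNF treatment signature.

Fits the paired MO3-BL contrast per cohort with precision weights and
empirical-Bayes moderation, tests cross-cohort concordance of the effect
profiles by sign-flip permutation, correlates effects with neutrophil
specificity scores, and estimates the paired CBC neutrophil/WBC ratio
change. The expected picture: a strongly concordant, neutrophil-negative
signature with the CBC ratio dropping to ~87% of baseline.
"""

import json
from pathlib import Path

from tnfblood import pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    cfg = pipeline.RunConfig(outdir=str(RESULTS / "treatment"), seed=SEED)
    res = pipeline.run_treatment_analysis(cfg)
    conc = res["concordance"]
    print(
        f"cross-cohort MO3-BL concordance: rho = {conc['rho']:.3f}, "
        f"permutation p = {conc['p']:.4g} ({conc['n_features']} genes, "
        f"{conc['n_permutations']} permutations)"
    )
    for cname, r in res["cohorts"].items():
        line = (
            f"{cname}: {r['n_significant']}/{r['n_genes_tested']} genes at "
            f"q < {cfg.fdr_level}; neutrophil specificity rho = "
            f"{r['neutrophil_specificity_rho']:.3f}"
        )
        if "nwr_mo3_percent_of_bl" in r:
            c = r["nwr_mo3_percent_of_bl"]
            line += (
                f"; CBC N/WBC at MO3 = {c['estimate']:.1f}% of BL "
                f"[{c['ci'][0]:.1f}, {c['ci'][1]:.1f}], p = {c['p']:.2g}"
            )
        print(line)
    with open(RESULTS / "treatment" / "summary.json", "w") as fh:
        json.dump(res, fh, indent=2, default=str)


if __name__ == "__main__":
    main()
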