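"""Generate the two synthetic study cohorts and write them under results/.

Emulates the study design: two independently processed cohorts of
biologic-naive RA patients starting anti-TNF (C1: 19 good responders + 21
non-responders; C2: 21 + 15), each sampled at baseline and month 3, with
whole-blood RNA counts, CBC values and clinical metadata, plus the ground
truth used by downstream recovery checks.
"""

from pathlib import Path

from tnfblood import pipeline, reference, simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"
SEED = 1


def main() -> None:
    cfg = pipeline.RunConfig(seed=SEED)
    ref = reference.generate_reference(
        cfg.n_genes, cfg.marker_fraction, seed=pipeline.subseed(SEED, 0)
    )
    OUT.mkdir(parents=True, exist_ok=True)
    ref.to_tsv(OUT / "reference_profiles.tsv", OUT / "reference_compartments.yaml")
    for i, (cname, (n_gr, n_nr)) in enumerate(cfg.n_subjects.items()):
        params = simulate.GeneratorParams(
            n_subjects_gr=n_gr,
            n_subjects_nr=n_nr,
            cohort=cname,
            seed=pipeline.subseed(SEED, 1 + i),
        )
        counts, meta, cbc, truth = simulate.generate_cohort(params, ref)
        simulate.write_cohort(OUT, counts, meta, cbc, truth, prefix=cname)
        print(
            f"{cname}: {counts.shape[0]} genes x {counts.shape[1]} samples "
            f"({n_gr} GR + {n_nr} NR subjects, BL+MO3); "
            f"true MO3:BL neutrophil ratio = "
            f"{params.treatment_neutrophil_multiplier}"
        )
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
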