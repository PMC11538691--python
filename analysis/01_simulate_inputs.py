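"""Generate every synthetic input the downstream analyses consume.

Builds, under scratch/fixtures/: a 1263-sequence screening cohort with the
published class structure (720 net-negative, 480 of those sparse-negative,
300 net-positive, 243 balanced), an 8-point NMR titration (K_D = 100 µM,
Δδmax = 0.2 ppm, [P] = 50 µM, 0.002 ppm noise), a six-delay relaxation
decay (R2 = 12 1/s, intensity noise sd 1), and a triplicate Bradford-path
sedimentation assay for three conditions at levels 0.8 / 0.64 / 0.4.
"""

import json
import sys
from pathlib import Path

from galphase import (AssaySpec, CohortSpec, DecaySpec, TitrationSpec,
                      make_assay, make_cohort, make_decay, make_titration)
from galphase.core_io import write_disorder_track, write_fasta, write_table

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "scratch" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cohort = CohortSpec(n_sequences=1263, n_net_negative=720,
                        n_net_positive=300, n_balanced=243,
                        n_negative_sparse=480, n_aromatic_rich=700,
                        seed=SEED)
    records, tracks, truth = make_cohort(cohort)
    write_fasta(records, OUT / "cohort.fasta")
    tracks_dir = OUT / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for rec in records:
        write_disorder_track(tracks[rec.id], rec, tracks_dir / f"{rec.id}.tsv")
    (OUT / "cohort_truth.json").write_text(json.dumps(truth, indent=2))
    print(f"cohort: {len(records)} sequences -> {OUT / 'cohort.fasta'}")

    series, t_truth = make_titration(TitrationSpec(noise_sd=0.002, seed=SEED))
    write_table([{"ligand_conc_uM": l, "delta_av_ppm": o}
                 for l, o in zip(series.ligand_concs, series.observed)],
                OUT / "titration.tsv",
                columns=["ligand_conc_uM", "delta_av_ppm"])
    (OUT / "titration_truth.json").write_text(json.dumps(t_truth, indent=2))
    print(f"titration: {len(series.ligand_concs)} points, "
          f"truth K_D = {t_truth['kd']} uM")

    decay, d_truth = make_decay(DecaySpec(noise_sd=1.0, seed=SEED))
    write_table([{"delay_s": t, "intensity": i}
                 for t, i in zip(decay.delays, decay.intensities)],
                OUT / "decay.tsv", columns=["delay_s", "intensity"])
    (OUT / "decay_truth.json").write_text(json.dumps(d_truth, indent=2))
    print(f"decay: {len(decay.delays)} delays, truth R2 = {d_truth['r2']} 1/s")

    standards, rows, a_truth = make_assay(AssaySpec(
        true_levels=(("WT", 0.8), ("GQQ", 0.64), ("GEE", 0.4)),
        ratio_noise_sd=0.005, seed=SEED))
    write_table([{"conc": c, "ratio": r} for c, r in standards],
                OUT / "standards.tsv", columns=["conc", "ratio"])
    write_table(rows, OUT / "assay.tsv",
                columns=["label", "replicate", "total_ratio",
                         "supernatant_ratio"])
    (OUT / "assay_truth.json").write_text(json.dumps(a_truth, indent=2))
    print(f"assay: {len(rows)} measurements over "
          f"{len(a_truth['true_levels'])} conditions")


if __name__ == "__main__":
    sys.exit(main())
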