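#!/usr/bin/env python
"""SEEG contact classification over the simulated response profiles.

Classifies one simulated contact per profile at a comfortable amplitude
(single-seed table, mirroring a small patient dataset), then measures
label-recovery rates over 100 seeds per separable profile at
amp = 10 x the local noise SD, plus the pure-FN false-positive rate on
null contacts and the behavior of the threshold-bound nonpure profile.
"""

import sys
import warnings
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

warnings.filterwarnings("ignore")

from fpvs import studies  # noqa: E402
from fpvs.pipeline import AnalysisConfig, classify_simulated_contacts  # noqa: E402

SEED = 7


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = AnalysisConfig(path="seeg", seed=SEED, seeg_amp=1.3)
    table = classify_simulated_contacts(cfg)
    table.round(3).to_csv(RESULTS / "contact_classification.tsv", sep="\t",
                          index=False)
    print("single-seed contact table (amp 1.3 μV per harmonic):")
    print(table[["profile", "truth", "label", "z_FN", "z_FO", "z_NO"]]
          .round(2).to_string(index=False))

    cls = studies.classification_study(n_seeds=100, seed=SEED)
    nonpure = studies.nonpure_study(n_seeds=50, seed=SEED)
    with open(RESULTS / "classification_recovery.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in {**cls, **nonpure}.items():
            fh.write(f"{k}\t{v}\n")
    print(f"\nlabel recovery at amp = 10 x noise SD "
          f"(sigma = {cls['noise_sd_uv']:.3f} μV, 100 seeds/profile):")
    for p in studies.SEPARABLE_PROFILES:
        print(f"  {p:15s} {cls[f'accuracy_{p}']:.0f}% correct")
    print(f"  null contacts labeled pure_FN: "
          f"{cls['null_pure_fn_rate_pct']:.1f}%")
    print(f"  nonpure profile: FN detected {nonpure['nonpure_fn_detect_pct']:.0f}%,"
          f" promoted to pure_FN {nonpure['nonpure_pure_fn_rate_pct']:.0f}%"
          f" (subtraction-Z floor bias; see docs/methods.md)")
    print(f"\ntables written to {RESULTS}")


if __name__ == "__main__":
    sys.exit(main())
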