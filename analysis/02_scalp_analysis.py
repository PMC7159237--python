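#!/usr/bin/env python
"""Scalp pipeline: preprocessing, spectra, ROI quantification, FN algebra.

Reads the simulated scalp session from 01_simulate.py, runs the full
preprocessing and frequency-domain chain, and writes the per-ROI
oddball quantification with the FN vs (FO + NO) contrast.  Also runs
the 20-subject grand-average condition (noise scaled by 1/sqrt(20)) to
show where the integration estimate lands at group-level SNR.
"""

import sys
import warnings
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "simulated"
RESULTS = ROOT / "results"

warnings.filterwarnings("ignore")

from fpvs import io, studies, synth  # noqa: E402
from fpvs.paradigm import ScheduleParams  # noqa: E402
from fpvs.pipeline import (AnalysisConfig, roi_condition_table,  # noqa: E402
                           scalp_condition_spectra)

SEED = 7


def main() -> None:
    path = SCRATCH / "scalp_session.h5"
    if not path.exists():
        print("run analysis/01_simulate.py first"); return 1
    cfg = AnalysisConfig()

    # single-session condition: re-simulate to recover block boundaries
    sim = synth.simulate_session(ScheduleParams(),
                                 studies.default_scalp_response(),
                                 n_sequences_per_condition=4, seed=SEED)
    spectra = scalp_condition_spectra(sim.recording, sim.block_boundaries,
                                      cfg=cfg)
    table = roi_condition_table(spectra, cfg)
    table.round(4).to_csv(RESULTS / "roi_quantification_single.tsv", sep="\t")
    io.write_spectrum(spectra["FN"], RESULTS / "fn_spectrum_low_band.tsv",
                      fmax=5.0)
    print("single-session ROI quantification (μV, baseline-corrected sum "
          "of 6 oddball harmonics):")
    print(table[["FN", "FO", "NO", "FO+NO", "integration_pct"]].round(3))
    print(f"  injected: FN 1.00, FO 0.38, NO 0.30 μV; crossmodal share 32%")

    group = studies.scalp_group_study(n_seeds=10, seed=SEED)
    with open(RESULTS / "integration_group.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in group.items():
            fh.write(f"{k}\t{v:.4f}\n")
    print("\n20-subject grand-average condition (median over 10 seeds):")
    print(f"  FN amplitude recovery ratio: {group['recovery_ratio']:.3f} "
          f"(Rayleigh-floor bias pulls it below 1)")
    print(f"  integration estimate: {group['integration_pct']:.1f}% "
          f"for an injected 32% (the same floor bias inflates the ratio)")
    print(f"\ntables written to {RESULTS}")


if __name__ == "__main__":
    sys.exit(main())
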