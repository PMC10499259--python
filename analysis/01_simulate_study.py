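#!/usr/bin/env python
"""Simulate a synthetic standing-and-walking emotion study.

Generates the demo-scale study (6 subjects x 5 emotion conditions, strong
injected effects) and writes its manifest under results/analysis/.  The
full-scale study conditions (24 subjects, 10 male, 3 relaxed + 1 fear trials
dropped) are what the test suite exercises; this driver keeps the artifact
small enough to regenerate in seconds.
"""

from pathlib import Path

from emogait import pipeline
from emogait.config import demo_config

OUT = Path("results/analysis")

if __name__ == "__main__":
    cfg = demo_config()
    study = pipeline.stage_simulate(cfg, OUT)
    trial, gt = study.generate("S01", "happy")
    print(f"study: {len(study.subjects)} subjects, {len(study.trial_plan)} trials")
    print(f"example trial S01/happy: {trial.markers.n_frames} marker frames "
          f"@ {trial.markers.rate:g} Hz, {trial.forceplate.n_samples} force "
          f"samples @ {trial.forceplate.rate:g} Hz")
    print(f"  ground truth: {len(gt.cop_locus_segments)} COP loci, "
          f"{len(gt.heel_strike_times['left']) + len(gt.heel_strike_times['right'])} "
          f"heel strikes, off-load at {gt.offload_time:.2f} s")
    print(f"manifest -> {OUT / 'study_manifest.json'}")
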