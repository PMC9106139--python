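"""Shared setup for the analysis drivers: the study cohort and its features.

The cohort mirrors the target study design — 15 subjects, two medication
conditions (OFF/ON), 32 channels, 512 Hz, 180 s — with a planted steeper
aperiodic slope in the ON condition over left-central channels and a
planted beta-band coupling increase between centro-parietal and frontal
pairs.  Features are cached under ``scratch/`` so the numbered scripts can
be run independently without recomputing.
"""

import pickle
import time
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "analysis"
SCRATCH = ROOT / "scratch"

from aperiodic_net.pipeline import AnalysisConfig, compute_cohort_features
from aperiodic_net.synthcohort import CohortSpec, CouplingEffect, generate_cohort

MASTER_SEED = 20220429


def study_spec() -> CohortSpec:
    return CohortSpec(
        coupling_effect=CouplingEffect(
            pairs=(("C3", "Pz"), ("Fz", "Pz"), ("C4", "CP2")),
            band=(13.0, 30.0),
            delta=0.25,
        ),
        seed=MASTER_SEED,
    )


def study_config() -> AnalysisConfig:
    return AnalysisConfig(seed=MASTER_SEED)


def get_cohort():
    return generate_cohort(study_spec())


def get_features(cohort=None, config=None):
    """Per-(subject, condition) features, cached across driver scripts."""
    cache = SCRATCH / "study_features.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    cohort = cohort or get_cohort()
    config = config or study_config()
    t0 = time.time()
    print("computing cohort features (30 recordings) ...", flush=True)
    features = compute_cohort_features(cohort, config)
    print(f"  done in {time.time() - t0:.0f} s")
    SCRATCH.mkdir(exist_ok=True)
    with open(cache, "wb") as fh:
        pickle.dump(features, fh)
    return features


def out_dir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
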