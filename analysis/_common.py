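"""Shared config and bundle cache for the numbered analysis drivers."""

from pathlib import Path
import pickle

from speechbeta.pipeline import PipelineConfig, run_pipeline
from speechbeta.synthetic import default_test_config

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = 1
N_SESSIONS = 10


def study_config() -> PipelineConfig:
    return PipelineConfig(sim=default_test_config(seed=SEED), n_sessions=N_SESSIONS)


def get_bundle():
    """Run (or load the cached) full pipeline on the study collection."""
    SCRATCH.mkdir(exist_ok=True)
    config = study_config()
    cache = SCRATCH / f"bundle_{config.config_hash()}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh), config
    bundle = run_pipeline(config)
    with open(cache, "wb") as fh:
        pickle.dump(bundle, fh)
    return bundle, config
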