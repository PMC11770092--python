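"""Shared plumbing for the numbered analysis drivers.

Each driver runs one pipeline stage against a shared working directory
(``results/analysis``) so the sequence 01..06 reproduces a full run; the
seed lives in the config written by 01.
"""

from pathlib import Path

from lepscan.pipeline import RunConfig, run_pipeline

WORKDIR = Path("results/analysis")
CONFIG = WORKDIR / "config.yaml"
DEFAULT_SEED = 20240901


def load_or_init_config() -> RunConfig:
    if CONFIG.exists():
        return RunConfig.from_yaml(CONFIG)
    cfg = RunConfig(outdir=str(WORKDIR), seed=DEFAULT_SEED)
    return cfg


def run_stage(stage: str) -> dict:
    cfg = load_or_init_config()
    cfg.stages = (stage,)
    report = run_pipeline(cfg)
    cfg.stages = ()  # stages are chosen per driver; keep config neutral
    WORKDIR.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(CONFIG)
    return report.stages[stage]
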