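"""Shared plumbing for the numbered analysis scripts: locations of the
synthetic study bundle and its pipeline outputs."""

import json
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"
CONFIG_PATH = DATA / "config.json"
SEED = 1


def load_config() -> dict:
    if not CONFIG_PATH.exists():
        raise SystemExit("run analysis/01_simulate_study.py first")
    from mmomics.pipeline import validate_config
    return validate_config(json.loads(CONFIG_PATH.read_text()))
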