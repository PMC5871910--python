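import pytest
from hypothesis import settings

import scwb

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from scwb.quant import QCThresholds, default_windows, quantify_profiles


def run_preset(name: str, seed: int = 0):
    """Simulate a preset cohort and run it through quantify/call/gate."""
    cfg = scwb.PRESETS[name](seed=seed)
    profiles, truth = scwb.generate_cohort(cfg)
    th = QCThresholds()
    windows = default_windows(sorted(profiles["target"].unique()),
                              model=cfg.model, thresholds=th)
    windows.setdefault("terbb2", th.window_terbb2)
    fits = quantify_profiles(profiles, windows, th)
    calls = scwb.call_isoform_table(fits)
    cells = scwb.gate_cells(fits, calls)
    return {"config": cfg, "profiles": profiles, "truth": truth,
            "fits": fits, "calls": calls, "cells": cells}


@pytest.fixture(scope="session")
def bt474_run():
    return run_preset("bt474", seed=0)


@pytest.fixture(scope="session")
def t0909_run():
    return run_preset("t0909", seed=0)


@pytest.fixture(scope="session")
def t0903_run():
    return run_preset("t0903", seed=0)


def planted_confusion(run: dict) -> tuple[int, int, int]:
    """(true positives, false positives, false negatives) for t-erbB2."""
    m = run["cells"].merge(run["truth"][["lane_id", "subpop_label"]],
                           on="lane_id")
    tp = int(((m.is_terbb2_pos) & (m.subpop_label == "terbb2")).sum())
    fp = int(((m.is_terbb2_pos) & (m.subpop_label != "terbb2")).sum())
    fn = int(((~m.is_terbb2_pos) & (m.subpop_label == "terbb2")).sum())
    return tp, fp, fn
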