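import json
from pathlib import Path
from types import SimpleNamespace

import pytest

from irneo.pipeline import simulate_study
from irneo.simulate import SimConfig


@pytest.fixture(scope="session")
def sim_study(tmp_path_factory):
    """The default synthetic study (20 genes, 50 tumor + 5 normal, seed 0),
    run end-to-end once and shared across tests."""
    out = tmp_path_factory.mktemp("sim_default")
    cfg = SimConfig(seed=0)
    ref, counts, clinical, loads, manifest = simulate_study(cfg, out)
    events = json.loads((Path(out) / "pipeline" / "events.json").read_text())
    return SimpleNamespace(
        cfg=cfg,
        ref=ref,
        counts=counts,
        clinical=clinical,
        loads=loads,
        manifest=manifest,
        events={s: set(v) for s, v in events.items()},
        out=Path(out),
    )
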