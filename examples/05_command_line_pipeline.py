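"""Drive the whole pipeline from a single YAML config via the CLI.

Equivalent shell usage:

    ramanres run-all --config run.yaml --out runs/demo --seed 7
"""

import json
import tempfile
from pathlib import Path

import yaml
from click.testing import CliRunner

from ramanres.cli import main

config = {
    "simulate": {"n_per_class": 30, "n_patients": 8},
    "model": {"stem_channels": 4, "n_stages": 5, "channel_cap": 8},
    "train": {"epochs": 2, "batch_size": 16, "learning_rate": 1e-3},
    "augment": {"copies_per_spectrum": 0},
    "global_seed": 7,
}

with tempfile.TemporaryDirectory() as tmp:
    cfg_path = Path(tmp) / "run.yaml"
    cfg_path.write_text(yaml.safe_dump(config))
    out = Path(tmp) / "run"

    result = CliRunner().invoke(
        main, ["run-all", "--config", str(cfg_path), "--out", str(out)]
    )
    assert result.exit_code == 0, result.output

    print("stage outputs:", sorted(p.name for p in out.iterdir()))
    metrics = json.loads((out / "metrics.json").read_text())
    print(f"ensemble test accuracy: {metrics['ensemble']['accuracy']:.3f}")
    members = ", ".join(
        "{} {:.3f}".format(k, v["accuracy"])
        for k, v in metrics.items()
        if k != "ensemble"
    )
    print("member accuracies:", members)
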