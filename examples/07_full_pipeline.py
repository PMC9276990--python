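"""Run the complete chain from one configuration and inspect the manifest.

Simulation -> moderated DE -> network modules -> ORA/GSEA -> regulator
enrichment -> key genes -> lasso model -> qPCR, all into one output
directory; rerunning with the same seed reproduces every file byte-wise.
"""

import json
import tempfile
from pathlib import Path

from modreg import run_pipeline, validate_config

config = validate_config({"seed": 1, "simulate": {}})
with tempfile.TemporaryDirectory() as tmp:
    rundir = run_pipeline(config, Path(tmp) / "run")
    manifest = json.loads((rundir / "manifest.json").read_text())
    print("files written:", ", ".join(sorted(p.name for p in rundir.iterdir())))
    for stage, info in manifest["stages"].items():
        print(f"{stage}: {info}")
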