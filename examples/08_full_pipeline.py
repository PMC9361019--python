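"""Run the complete analysis end-to-end with one config and inspect the
manifest.  Equivalent CLI: `hccstem run-all --seed 11 --outdir out/`.
"""

import json
from pathlib import Path

from hccstem import PipelineConfig, run_full_pipeline

cfg = PipelineConfig(seed=11, outdir="pipeline_out")
manifest = run_full_pipeline(cfg)

print(f"status: {manifest['status']}; {len(manifest['outputs'])} outputs in {cfg.outdir}/")
for name, entry in manifest["outputs"].items():
    extras = {k: v for k, v in entry.items() if k not in ("path", "sha256")}
    print(f"  {name:26s} {entry['path']:32s} {extras if extras else ''}")

roc = json.loads((Path(cfg.outdir) / "signature_roc.json").read_text())
surv = json.loads((Path(cfg.outdir) / "survival_tests.json").read_text())
print(f"\nsignature AUC = {roc['auc']:.3f}; log-rank p = {surv['logrank_p']:.3g}")
# Re-running with the same config reproduces every table byte-for-byte;
# the manifest records the parameters and seed needed to re-run any
# stage in isolation.
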