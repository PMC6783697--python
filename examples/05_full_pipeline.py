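"""Run the whole pipeline from one configuration and render its report.

Chains synthesis, ingestion, concordance analysis, cell-parameter derivation
and composition building, then prints the markdown report assembled purely
from the artifact files on disk.
"""

import tempfile
from pathlib import Path

from cytocomp import RunConfig, render_report, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig(out_dir=str(Path(tmp) / "run"), seed=7)
    artifacts = run_pipeline(config)

    print("artifacts written:")
    for path in sorted(artifacts.rglob("*")):
        if path.is_file():
            print(f"  {path.relative_to(artifacts)}")

    print("\n" + render_report(artifacts))
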