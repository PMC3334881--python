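"""Run the whole pipeline from a YAML config and print the report.

Equivalent shell command:  srnameth run -c examples/demo_config.yaml -o out
"""

from pathlib import Path

from srnameth import run_pipeline

here = Path(__file__).parent
out = run_pipeline(here / "demo_config.yaml", here.parent / "scratch" / "demo_run")
print((out / "report.txt").read_text())
print(f"stage tables and manifest written to {out}")
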