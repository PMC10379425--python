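#!/usr/bin/env python
"""Full reproduction report over both packaged Palaemon fixtures.

Chains annotation statistics, gene-order comparison and (where sequence is
available) composition/RSCU into one Markdown report with MATCH/MISMATCH
flags against the published values.
"""

from pathlib import Path

from mitocomp.report import RunConfig, run_full_report

OUT = Path(__file__).resolve().parent.parent / "results" / "report"
report = run_full_report(RunConfig(outdir=OUT))
print(report.read_text())
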