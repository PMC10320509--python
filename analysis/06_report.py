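"""Full pipeline plus the summary statistics report (correlation summaries,
KS test, robustness state comparisons)."""
from _common import run_stage

if __name__ == "__main__":
    run_stage("report", "results/06_report", __doc__)
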