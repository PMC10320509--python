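"""Bin spikes, compute filtered rates, envelope tuning, STA polarity and
pairwise rate correlations for both states."""
from _common import run_stage

if __name__ == "__main__":
    run_stage("process", "results/02_process", __doc__)
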