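"""Simulate the paired control/inactivated sessions and dump spike trains,
stimulus traces and session metadata."""
from _common import run_stage

if __name__ == "__main__":
    run_stage("simulate", "results/01_simulate", __doc__, save_spikes=True)
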