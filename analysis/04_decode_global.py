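"""Fit the global (fish) behavior decoders with differential evolution and
evaluate the control-trained weights on both states."""
from _common import run_stage

if __name__ == "__main__":
    run_stage("decode_global", "results/04_decode_global", __doc__)
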