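"""Fit the per-condition optimal linear stimulus decoders and evaluate them
on the held-out trial half."""
from _common import run_stage

if __name__ == "__main__":
    run_stage("decode_local", "results/03_decode_local", __doc__)
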