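"""Weight-noise robustness curves and attenuation slopes for the local and
global decoders in both states."""
from _common import run_stage

if __name__ == "__main__":
    run_stage("robustness", "results/05_robustness", __doc__)
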