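"""Parameter and MAC accounting for the default backbone.

Builds the calibrated default model (3 classes, 224 x 224 input) and prints
the per-segment complexity breakdown.  The totals — about 25.2 million
trainable parameters and 6.4 billion multiply-accumulates per image — are
the architecture's published complexity budget; the per-stage rows show how
depth is concentrated in the penultimate stage.
"""

from gcanet import ModelConfig, build_model, complexity_report

model = build_model(ModelConfig())
report = complexity_report(model, 224)
print(report)
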