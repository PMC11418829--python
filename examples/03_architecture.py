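"""Inspect the 3D convolutional architecture: shapes and parameter counts.

For a (12, 128, 128, 1) kinematic input the network collapses time and
space through five strided 3x3x3 convolutions, then two 1024-unit dense
layers; the last hidden dense layer is the embedding descriptor.
"""

from cardiokin import build_architecture, count_parameters, total_parameters

spec = build_architecture(in_channels=1, n_classes=2)
shapes = spec.output_shapes()
print(f"{'layer':<10}{'output shape':<20}{'parameters':>12}")
for layer in spec.layers:
    print(f"{layer.name:<10}{str(shapes[layer.name]):<20}"
          f"{count_parameters(spec, layer.name):>12,}")
print(f"total trainable parameters: {total_parameters(spec):,}")
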