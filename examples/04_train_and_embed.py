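"""Train a small classifier on phantoms and probe its embedding space.

Trains the (width-reduced) 3D convolutional network to separate normal
from dilated-cardiomyopathy-like phantoms using the divergence channel,
then extracts the hidden dense-layer embeddings and shows that the two
classes separate geometrically (between-class distances exceed
within-class ones).  Runs in about two minutes on one CPU.
"""

import numpy as np

from cardiokin import (TrainConfig, build_architecture, extract_embedding,
                       generate_cohort, predict, train_binary)
from cardiokin.evaluation import PipelineConfig, prepare_cohort

config = PipelineConfig.reduced(channels=("div",))
cohort = [s for s in generate_cohort(4, seed=11) if s.label in ("N", "DCM")]
samples = prepare_cohort(cohort, config)
stacks = [s.stacks["div"] for s in samples]

spec = build_architecture(in_channels=1, n_classes=2,
                          input_shape=stacks[0].shape[:3],
                          filters=config.filters,
                          dense_units=config.dense_units)
model = train_binary(stacks, config=TrainConfig(epochs=8), seed=0, spec=spec)
print(f"loss per epoch: {[round(l, 4) for l in model.loss_history]}")

preds = [model.classes[int(np.argmax(predict(model, s)))] for s in stacks]
acc = np.mean([p == s.label for p, s in zip(preds, stacks)])
print(f"training accuracy: {acc:.2f}")

embs = {lab: [extract_embedding(model, s).values
              for s in stacks if s.label == lab] for lab in ("N", "DCM")}
within = np.mean([np.linalg.norm(a - b)
                  for grp in embs.values()
                  for i, a in enumerate(grp) for b in grp[i + 1:]])
between = np.mean([np.linalg.norm(a - b)
                   for a in embs["N"] for b in embs["DCM"]])
print(f"mean embedding distance within classes {within:.2f}, "
      f"between classes {between:.2f} (separation: {between > within})")
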