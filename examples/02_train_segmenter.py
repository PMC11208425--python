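"""Train a small residual U-Net on noiseless phantoms (a few minutes on CPU).

Eight phantom studies train the model, two are held out; the printed
validation Dice is the mean over muscle classes across held-out slices.
"""

from muscleidp.datasets import studies_from_phantoms
from muscleidp.phantom import PhantomSpec, make_phantom_set
from muscleidp.segmenter import SegmenterConfig, TrainConfig, build_segmenter, train

phantoms = make_phantom_set(10, seed=1, base_spec=PhantomSpec(hu_noise_sd=0.0))
studies = studies_from_phantoms(phantoms)
train_set, val_set = studies[:8], studies[8:]
print(f"training on {sum(s.images.shape[0] for s in train_set)} slices, "
      f"validating on {sum(s.images.shape[0] for s in val_set)}")

cfg = TrainConfig(lr_schedule=((10, 1e-3),), augmentation=None, batch_size=8, seed=0)
model = build_segmenter(SegmenterConfig(residual_units=2, base_channel_width=8), seed=0)
model, history = train(model, train_set, val_set, cfg)

for epoch, (loss, d) in enumerate(zip(history["train_loss"], history["val_dice"]), 1):
    print(f"epoch {epoch:2d}: train soft-Dice loss {loss:.4f}, validation Dice {d:.3f}")
print("\nA Dice of 1.0 is perfect overlap with ground truth; ~0.9 on these")
print("phantoms means the network has learned the anatomy layout, not merely")
print("the attenuation threshold.")
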