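"""Train a small mask-to-fundus translation model and synthesize an image.

A ResU-net generator (U-net with one residual block per resolution level)
is trained adversarially against a patch discriminator with the combined
objective: non-saturating adversarial term + 0.5 * L1 to the paired
photograph, Adam at learning rate 2e-4 with beta1 = 0.5, batch size 1.
Scaled down to 64 x 64 and a narrow network so it runs in well under a
minute on a laptop CPU.
"""

from fundusgan import (
    DiscriminatorSpec,
    GeneratorSpec,
    PhantomParams,
    RandomizeFlags,
    TrainConfig,
    generate_dataset,
    prepare_paired,
    synthesize,
    train_pix2pix,
)

samples = generate_dataset(4, PhantomParams(image_size=64, seed=0),
                           RandomizeFlags(), seed=0)
data = prepare_paired(samples, "mcml")

config = TrainConfig(
    mode="pix2pix",
    input_encoding="mcml",
    generator=GeneratorSpec(family="resunet", in_channels=3, base_width=8,
                            depth=3, n_res_blocks=1),
    discriminator=DiscriminatorSpec(in_channels=6, base_width=16, n_layers=3),
    epochs=25,
    seed=0,
    image_size=64,
)
result = train_pix2pix(data, config, out_dir="out_train")

first = [r["l1"] for r in result.history[:4]]
last = [r["l1"] for r in result.history[-4:]]
print(f"L1 reconstruction error (normalized units): "
      f"first epoch mean {sum(first) / 4:.3f} -> last epoch mean {sum(last) / 4:.3f}")

image = synthesize(result.checkpoint_path, data[0][1])
print("synthesized image:", image.shape, image.dtype,
      "intensity range", (int(image.min()), int(image.max())))
# The falling L1 shows the generator learning the mask -> photograph mapping;
# the synthesized array is a standard 8-bit RGB image.
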