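"""Featurize one second of audio and print the CNN parameter accounting.

A one-second clip becomes a 49x40 log-mel image (49 overlapping 30 ms
slices x 40 mel bins, quantized 0-255).  The default network maps that
image to 3 classes with 18,363 parameters, small enough for an MCU with
a few hundred KB of SRAM.
"""

import numpy as np

from mozznet import FeatureExtractor, WingbeatSpec, build_model, count_parameters, gen_mosquito


def main():
    clip = gen_mosquito(WingbeatSpec(sex="female", fundamental_hz=450.0, seed=0))
    image = FeatureExtractor().clip_to_image(clip)
    print(f"spectrogram image: {image.shape}, dtype {image.dtype}")
    hot = np.argmax(image.mean(axis=0))
    print(f"most energetic mel bin: {hot} (holds the 450 Hz fundamental)\n")

    reports, n_w, n_b, total = count_parameters(build_model())
    print(f"{'layer':>8} {'tensor':>12} {'weights':>8} {'biases':>7} {'params':>7}")
    for r in reports:
        size = "x".join(str(d) for d in r.tensor_size)
        print(f"{r.name:>8} {size:>12} {r.n_weights:>8} {r.n_biases:>7} {r.n_params:>7}")
    print(f"{'Total':>8} {'':>12} {n_w:>8} {n_b:>7} {total:>7}")


if __name__ == "__main__":
    main()
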