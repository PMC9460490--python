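"""Generate synthetic wingbeat and household-noise clips and inspect them.

Builds one female wingbeat clip, one pink-noise background clip and one
refrigerator-hum clip, writes them as WAV files, and prints the dominant
spectral peak and RMS level of each — the peak should sit at the drawn
wingbeat fundamental (400-500 Hz for a female) and the levels should
reflect the nominal dB settings.
"""

import numpy as np

from mozznet import NoiseKind, NoiseSpec, WingbeatSpec, gen_mosquito, gen_noise, write_wav


def dominant_hz(clip):
    spectrum = np.abs(np.fft.rfft(clip.samples))
    return np.argmax(spectrum) * clip.sample_rate / len(clip.samples)


def main():
    mosquito = gen_mosquito(WingbeatSpec(sex="female", duration_s=2.0, seed=1))
    pink = gen_noise(NoiseSpec(NoiseKind.SILENCE_PINK, duration_s=2.0, seed=1))
    fridge = gen_noise(NoiseSpec(NoiseKind.REFRIGERATOR, duration_s=2.0, seed=1))

    for name, clip in [("mosquito", mosquito), ("pink", pink), ("refrigerator", fridge)]:
        write_wav(clip, f"{name}.wav")
        print(
            f"{name:>12}: label={clip.label.name:<8} peak={dominant_hz(clip):7.1f} Hz "
            f"rms={clip.rms():.2e}"
        )
    print(
        "\nThe mosquito peak is the wingbeat fundamental; the refrigerator "
        "peaks at its 60 Hz mains hum (or a harmonic); pink noise has no "
        "single dominant tone."
    )


if __name__ == "__main__":
    main()
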