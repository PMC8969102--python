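"""Turn a recording into the 3-channel spectrogram image the image encoder eats.

Builds a 2 s 440 Hz tone, computes its 224-band log-Mel spectrogram with the
package defaults (hop 1024, Hann window), stacks log-Mel/delta/delta-delta
and resizes to 224 x 224.
"""

import numpy as np

from demfusion import Waveform, compute_log_mel, waveform_to_image

sr = 16_000
t = np.arange(2 * sr) / sr
tone = Waveform(0.5 * np.sin(2 * np.pi * 440.0 * t), sr)

mel = compute_log_mel(tone)
print(f"log-Mel matrix: {mel.values.shape[0]} bands x {mel.values.shape[1]} frames (dB)")

img = waveform_to_image(tone)
print(f"spectrogram image: {img.channels.shape}, channels = {img.channel_roles}")
print(f"channel value ranges after normalization: "
      f"{[np.round((c.min(), c.max()), 2).tolist() for c in img.channels]}")
# The first channel localizes the tone's energy in one Mel band; the delta
# channels are ~constant because a steady tone has no temporal dynamics.
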