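"""Gate skin pixels of a frame by their hue and Cb/Cr chroma.

A pixel is skin when 1 <= H <= 23 (half-degree hue), 77 <= Cb <= 127 and
133 <= Cr <= 173 (full-range BT.601). The synthetic patch passes the gate;
the gray textured background does not.
"""

import numpy as np

from ippg import spatial, synth

seq, _ = synth.generate(synth.Scenario(seed=3, frame_size=(60, 80), duration_s=1.0))
frame = seq.frames[0]

raw = spatial.detect_skin(frame)
cleaned = spatial.clean_mask(raw)

h = spatial.hue_halfdeg(frame)
cb, cr = spatial.cb_cr(frame)
ys, xs = np.nonzero(cleaned.mask)
print(f"raw gate coverage     : {raw.coverage:.1%} of pixels")
print(f"after 3x3 cleanup     : {cleaned.coverage:.1%} (largest connected blob)")
print(f"skin-pixel hue range  : {h[ys, xs].min():.1f} .. {h[ys, xs].max():.1f} (half-degrees)")
print(f"skin-pixel Cb range   : {cb[ys, xs].min():.1f} .. {cb[ys, xs].max():.1f}")
print(f"skin-pixel Cr range   : {cr[ys, xs].min():.1f} .. {cr[ys, xs].max():.1f}")
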