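"""Build the pRF-mapping bar stimulus and inspect its structure.

A 2-degree bar sweeps across an 11.5-degree-radius field on four axes with
two directions each, with mean-luminance blanks interleaved; predictions are
made at the fMRI sampling rate (TR = 2 s).
"""

import numpy as np

import eccmap as em

geometry = em.FieldGeometry(radius=11.5, grid_n=101)
movie = em.make_bar_apertures(geometry, bar_width=2.0)
movie_tr = em.resample_to_tr(movie, tr=2.0)

print(f"sweep segments: {movie.n_sweeps} "
      "(4 axes x 2 directions, the standard 8-sweep protocol)")
print(f"run duration:   {movie.duration:.0f} s "
      f"({movie.n_frames} frames at 4 Hz -> {movie_tr.n_frames} TR bins)")
frac = movie.frames.mean()
print(f"mean aperture fill: {frac:.3f} "
      "(fraction of the model grid lit, averaged over the run)")
blank = (movie.sweep_labels == -1).mean()
print(f"blank time:     {100 * blank:.0f}% of frames show the gray background")
outside = movie.frames[:, ~geometry.disc_mask()].sum()
print(f"energy outside the stimulus disc: {outside:.0f} (must be 0)")
assert np.all(np.diff(movie.times) > 0)
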