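"""Two-regime split fit of a high-concentration condensation trace.

Above the ~400 uM cross-link threshold the SS trace starts as a
double-exponential decay (diadducts + micro-loops) and switches to a
single-exponential regime once long-range cross-links take over.  The split
fit locates the regime boundary and fits the two parts independently.
"""

import warnings

import ptdna

warnings.simplefilter("ignore", RuntimeWarning)

spec = {"head": {"plateau": 3.5, "amplitudes": [3.4, 6.8],
                 "time_constants": [6.07, 76.23]},   # SS-like, 600 uM
        "tail": {"plateau": 2.0, "time_constant": 146.98},
        "breakpoint_min": 120.0}
ts = ptdna.gen_extension_timeseries(
    spec, duration_min=600.0,
    noise=ptdna.NoiseModel("additive-gaussian", 0.27), seed=5)

split = ptdna.split_exponential_fit(ts)
print(f"regime change detected: {split.regime_change}")
print(f"breakpoint at {split.breakpoint_time_min:.0f} min "
      f"(generator: 120)")
print("head (double):  T1 = {:6.2f}, T2 = {:6.2f} min".format(
    *split.head_fit.time_constants_min))
print(f"tail (single):  T  = {split.tail_fit.time_constants_min[0]:6.2f} min "
      f"(generator 146.98)")
# The tail constant is the cross-link formation time scale; recovering it
# within ~10% shows the split fit isolates the late regime correctly.
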