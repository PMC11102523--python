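"""Published best-fit parameter sets for three YouTube music videos.

These are the calibrated rates for "Caroline", "Cheap Thrills" and
"All About That Bass" fitted against their daily-view series with
S0 = 2e9 (the platform's public active-user count) and I0 = 100 initial
sharers.  The underlying view series are not redistributable, so the sets
serve as reference fixtures: the ``beta1/beta`` column characterizes how
readily a listener becomes an active sharer of each song, and ``er`` is the
normalized least-squares cost of the published fit.
"""

from __future__ import annotations

from .params import ModelParams

__all__ = ["CASE_STUDY_S0", "CASE_STUDY_I0", "CASE_STUDY_FITS"]

CASE_STUDY_S0 = 2e9
CASE_STUDY_I0 = 100.0

CASE_STUDY_FITS: dict[str, dict] = {
    "caroline": {
        "params": ModelParams(beta=7.9561, beta1=0.3987, alpha=0.3876, b=5.5e-5, gamma=7.5e-8),
        "er": 4.98e-5,
    },
    "cheap_thrills": {
        "params": ModelParams(beta=8.9792, beta1=0.0911, alpha=0.0870, b=2.0e-4, gamma=1.9e-6),
        "er": 4.60e-6,
    },
    "all_about_that_bass": {
        "params": ModelParams(beta=0.0302, beta1=0.0220, alpha=0.0012, b=3.3e-4, gamma=4.4e-4),
        "er": 1.62e-5,
    },
}
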