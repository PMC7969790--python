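"""Periodic limb-cycle waveforms with closed-form extrema and range.

The sagittal angle of a distal limb segment over one stride is modelled as a
unit peak-to-peak periodic function of cycle position ``c`` (percent of stride,
[0, 100)).  Two families are provided:

``asymmetric``
    Two cosine half-arcs joined C1-continuously: a rising arc from the
    retraction minimum at ``minimum_pct`` to the protraction maximum at
    ``maximum_pct`` and a falling arc back.  This places both extrema at
    arbitrary cycle positions while keeping the peak-to-peak range exactly 1.

``sinusoid``
    ``-cos`` with its minimum at ``minimum_pct`` (maximum fixed 50% later).
"""

from __future__ import annotations

import numpy as np


def cycle_waveform(c, minimum_pct: float, maximum_pct: float, kind: str = "asymmetric"):
    """Evaluate the unit waveform and its derivative w.r.t. cycle position.

    Parameters
    ----------
    c : array-like
        Cycle positions in percent (any real values; wrapped mod 100).
    minimum_pct, maximum_pct : float
        Cycle positions of the minimum (maximal retraction) and maximum
        (maximal protraction), in [0, 100).
    kind : {"asymmetric", "sinusoid"}

    Returns
    -------
    w, dw : ndarray
        Waveform value (peak-to-peak 1, extrema at -0.5/+0.5) and derivative
        per percent of cycle.
    """
    c = np.asarray(c, dtype=float)
    rel = np.mod(c - minimum_pct, 100.0)
    if kind == "sinusoid":
        w = -0.5 * np.cos(2 * np.pi * rel / 100.0)
        dw = (np.pi / 100.0) * np.sin(2 * np.pi * rel / 100.0)
        return w, dw
    if kind != "asymmetric":
        raise ValueError(f"unknown waveform kind {kind!r}")
    d = np.mod(maximum_pct - minimum_pct, 100.0)
    if d == 0.0:  # degenerate placement: fall back to the symmetric shape
        return cycle_waveform(c, minimum_pct, minimum_pct + 50.0, kind="sinusoid")
    rising = rel < d
    w = np.empty_like(rel)
    dw = np.empty_like(rel)
    u = rel[rising] / d
    w[rising] = -0.5 * np.cos(np.pi * u)
    dw[rising] = 0.5 * (np.pi / d) * np.sin(np.pi * u)
    v = (rel[~rising] - d) / (100.0 - d)
    w[~rising] = 0.5 * np.cos(np.pi * v)
    dw[~rising] = -0.5 * (np.pi / (100.0 - d)) * np.sin(np.pi * v)
    return w, dw
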