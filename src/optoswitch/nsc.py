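"""Normalized slope conductance (NSC) of current-density-voltage relations.

The NSC compares the *shape* of I-V relations independently of current
amplitude: each curve is fitted with a cubic smoothing spline, the inward
(V < 0) and outward (V > 0) branches are normalised to percent of their
value at the -100 / +100 mV anchors, and the voltage-wise derivative of the
normalised curve — evaluated analytically from the spline coefficients — is
rescaled so its branch mean is 1.  An ohmic conductor therefore has NSC = 1
everywhere; deviations localise the voltages where gating differs between
stimuli.  Group differences are tested per voltage with rank tests
(two groups: Mann-Whitney U; three or more: Kruskal-Wallis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline

from .recordings import IVCurve


@dataclass
class SmoothedIV:
    voltage_mV: np.ndarray
    density_pApF: np.ndarray
    spline: BSpline
    lam: float | None
    residual_sse: float
    source_id: str = ""


@dataclass
class NSCCurve:
    """Per-branch normalised density (%) and normalised slope conductance."""

    voltage_mV: np.ndarray
    normalized_pct: np.ndarray
    nsc: np.ndarray
    branch: np.ndarray  # "inward" / "outward" per grid point
    endpoint_flag: np.ndarray  # True where the derivative is one-sided
    cell_id: str = ""
    group: str = ""
    meta: dict = field(default_factory=dict)


@dataclass
class NSCComparison:
    voltage_mV: np.ndarray
    p_value: np.ndarray
    test: str
    group_sizes: tuple
    groups: tuple


def smooth_iv(iv: IVCurve, lam: float | None = None) -> SmoothedIV:
    """Cubic smoothing spline of an I-V relation.

    ``lam`` is the roughness penalty; ``None`` selects it by generalised
    cross-validation.  The spline is evaluated on the source grid.
    """
    v = np.asarray(iv.voltage_mV, float)
    d = np.asarray(iv.density_pApF, float)
    if v.size < 10:
        raise ValueError("need at least 10 grid points to smooth")
    if np.ptp(v) == 0:
        raise ValueError("degenerate (constant-voltage) input")
    spline = make_smoothing_spline(v, d, lam=lam)
    smoothed = spline(v)
    return SmoothedIV(
        voltage_mV=v,
        density_pApF=smoothed,
        spline=spline,
        lam=lam,
        residual_sse=float(np.sum((smoothed - d) ** 2)),
        source_id=iv.sweep_id,
    )


def _branch_masks(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return v < 0.0, v > 0.0


def normalize_iv(smoothed: SmoothedIV) -> dict:
    """Branch-anchored percent normalisation of a smoothed I-V relation.

    The inward branch is scaled so the most negative grid voltage maps to
    -100%, the outward branch so the most positive maps to +100%; V = 0 maps
    to 0%.  Scaling each branch by its own anchor deliberately discards the
    rectification ratio — only curve shape survives.
    """
    v = smoothed.voltage_mV
    d = smoothed.density_pApF
    inward, outward = _branch_masks(v)
    if not np.any(inward) or not np.any(outward):
        raise ValueError("need grid points on both sides of 0 mV")
    d_in_anchor = d[inward][0]  # most negative voltage
    d_out_anchor = d[outward][-1]  # most positive voltage
    if d_in_anchor == 0.0 or d_out_anchor == 0.0:
        raise ValueError("no current at an anchor potential")
    scale_in = -100.0 / d_in_anchor
    scale_out = 100.0 / d_out_anchor
    norm = np.zeros_like(d)
    norm[inward] = d[inward] * scale_in
    norm[outward] = d[outward] * scale_out
    return {
        "voltage_mV": v,
        "normalized_pct": norm,
        "scale_inward": scale_in,
        "scale_outward": scale_out,
        "spline": smoothed.spline,
        "source_id": smoothed.source_id,
    }


def compute_nsc(normalized: dict, cell_id: str = "", group: str = "") -> NSCCurve:
    """Normalised slope conductance from a branch-normalised curve.

    The derivative d(normalised density)/dV comes analytically from the
    smoothing spline's coefficients (scaled per branch); each branch is then
    rescaled so its mean NSC is 1.  V = 0 is excluded (its normalisation is
    degenerate) and branch endpoints are flagged as one-sided.
    """
    v = np.asarray(normalized["voltage_mV"], float)
    deriv = normalized["spline"].derivative()
    inward, outward = _branch_masks(v)
    keep = inward | outward  # drop V == 0
    v_out = v[keep]
    slopes = np.empty(v_out.size)
    branch = np.empty(v_out.size, dtype=object)
    endpoint = np.zeros(v_out.size, dtype=bool)
    pos = 0
    for mask, scale, name in (
        (inward, normalized["scale_inward"], "inward"),
        (outward, normalized["scale_outward"], "outward"),
    ):
        vb = v[mask]
        sb = deriv(vb) * scale
        mean = np.mean(sb)
        if mean == 0.0:
            raise ValueError(f"zero mean slope on the {name} branch")
        slopes[pos : pos + vb.size] = sb / mean
        branch[pos : pos + vb.size] = name
        endpoint[pos] = endpoint[pos + vb.size - 1] = True
        pos += vb.size
    norm_pct = np.asarray(normalized["normalized_pct"], float)[keep]
    return NSCCurve(
        voltage_mV=v_out,
        normalized_pct=norm_pct,
        nsc=slopes,
        branch=branch,
        endpoint_flag=endpoint,
        cell_id=cell_id,
        group=group,
        meta={
            "scale_inward": normalized["scale_inward"],
            "scale_outward": normalized["scale_outward"],
        },
    )


def nsc_from_iv(
    iv: IVCurve, lam: float | None = None, cell_id: str = "", group: str = ""
) -> NSCCurve:
    """Convenience pipeline: smooth -> normalise -> NSC for one I-V curve."""
    return compute_nsc(normalize_iv(smooth_iv(iv, lam=lam)), cell_id=cell_id, group=group)


def compare_nsc(
    groups: dict[str, Sequence[NSCCurve]],
    holm: bool = False,
) -> NSCComparison:
    """Per-voltage rank test of NSC values between groups of cells.

    Two groups are compared with the Mann-Whitney U test, three or more
    with Kruskal-Wallis.  p values are pointwise by default (``holm=True``
    adds a Holm correction across voltages).
    """
    from .stats import kruskal_wallis, mann_whitney_u

    names = tuple(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    sizes = tuple(len(groups[n]) for n in names)
    if any(s < 3 for s in sizes):
        raise ValueError("each group needs at least 3 cells")
    grid = np.asarray(groups[names[0]][0].voltage_mV, float)
    for n in names:
        for c in groups[n]:
            if not np.array_equal(np.asarray(c.voltage_mV, float), grid):
                raise ValueError("all NSC curves must share one voltage grid")
    p = np.empty(grid.size)
    for i in range(grid.size):
        samples = [np.array([c.nsc[i] for c in groups[n]]) for n in names]
        if len(names) == 2:
            p[i] = mann_whitney_u(samples[0], samples[1]).p_value
            test = "mann-whitney-u"
        else:
            p[i] = kruskal_wallis(samples).p_value
            test = "kruskal-wallis"
    if holm:
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        p = adj
    return NSCComparison(
        voltage_mV=grid, p_value=p, test=test, group_sizes=sizes, groups=names
    )
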