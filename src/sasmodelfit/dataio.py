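"""Reading, merging, masking and annotating 1-D scattering curves.

A scattering curve is three columns: the magnitude of the scattering vector
``q``, the intensity ``I(q)`` and the uncertainty on the intensity
``sigma``.  All operations here are unit agnostic: values are kept in
whatever units the file supplies and no conversion ever happens implicitly.

Input files are plain ASCII.  Any line whose tokens all parse as floating
point numbers is treated as data; every other line (headers, comments,
PDH-style metadata) is skipped silently but counted in the curve's log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SASCurve",
    "read_curve",
    "estimate_sigma",
    "merge_curves",
    "write_curve",
]

#: default moving-window length for uncertainty estimation
SIGMA_WINDOW = 11


def _frozen(a: np.ndarray) -> np.ndarray:
    a = np.array(a, dtype=float)
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class OriginalData:
    """Untouched copy of a curve as first constructed.

    Reduction and masking never mutate these arrays; they are carried along
    for traceability so the working view can always be discarded.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None
    source: tuple

    @classmethod
    def capture(cls, q, I, sigma, source):
        return cls(
            _frozen(q),
            _frozen(I),
            None if sigma is None else _frozen(sigma),
            tuple(source),
        )


@dataclass
class SASCurve:
    """One scattering data set (q, I, sigma) plus provenance.

    ``q`` is strictly positive and, after :func:`merge_curves`, sorted
    ascending (duplicates allowed).  ``sigma`` may be ``None`` until
    :func:`estimate_sigma` supplies positive uncertainties.  ``original``
    holds the data exactly as first read/constructed; every operation
    returns a new curve and leaves it untouched.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    source: tuple = ()
    original: OriginalData | None = None
    log: list = field(default_factory=list)
    flags: set = field(default_factory=set)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if not self.source:
            self.source = tuple("<memory>" for _ in self.q)
        if self.original is None:
            self.original = OriginalData.capture(self.q, self.I, self.sigma, self.source)

    def __len__(self) -> int:
        return self.q.size

    @property
    def n_points(self) -> int:
        return self.q.size

    def _derive(self, q, I, sigma, source, note: str) -> "SASCurve":
        cur = SASCurve.__new__(SASCurve)
        cur.q = np.asarray(q, dtype=float)
        cur.I = np.asarray(I, dtype=float)
        cur.sigma = None if sigma is None else np.asarray(sigma, dtype=float)
        cur.source = tuple(source)
        cur.original = self.original
        cur.log = self.log + [note]
        cur.flags = set(self.flags)
        return cur

    def with_window(self, qlo: float | None, qhi: float | None) -> "SASCurve":
        """Working view restricted to qlo <= q <= qhi (either bound optional)."""
        lo = -np.inf if qlo is None else qlo
        hi = np.inf if qhi is None else qhi
        keep = (self.q >= lo) & (self.q <= hi)
        if not keep.any():
            raise ValueError("empty data set: no points inside q window "
                             f"[{lo:g}, {hi:g}]")
        return self._derive(
            self.q[keep], self.I[keep],
            None if self.sigma is None else self.sigma[keep],
            [s for s, k in zip(self.source, keep) if k],
            f"window [{lo:g}, {hi:g}]: kept {int(keep.sum())}/{len(keep)}",
        )

    def restore_original(self) -> "SASCurve":
        """Discard every reduction/mask and return the as-read data."""
        o = self.original
        return self._derive(o.q.copy(), o.I.copy(),
                            None if o.sigma is None else o.sigma.copy(),
                            o.source, "restored original")


def _parse_lines(lines, column_map):
    """Extract the numeric block: lines whose tokens are all floats."""
    idx = {name: i for i, name in enumerate(column_map)}
    if "q" not in idx or "I" not in idx:
        raise ValueError("column_map must name at least 'q' and 'I'")
    need = max(idx.values()) + 1
    rows, skipped = [], 0
    for line in lines:
        tokens = line.replace(",", " ").replace(";", " ").split()
        if not tokens:
            skipped += 1
            continue
        try:
            vals = [float(t) for t in tokens]
        except ValueError:
            skipped += 1
            continue
        if len(vals) < need:
            skipped += 1
            continue
        rows.append(vals)
    return rows, skipped, idx


def read_curve(path, column_map=("q", "I", "sigma"), q_window=None) -> SASCurve:
    """Read a 3-column ASCII / PDH-dialect scattering curve.

    Parameters
    ----------
    path : str or Path
        File to read.  Whitespace-, comma- or semicolon-separated columns.
    column_map : sequence of str
        Content of each column in file order; must contain ``"q"`` and
        ``"I"``, optionally ``"sigma"``.  E.g. ``("I", "q", "sigma")``.
    q_window : (qlo, qhi), optional
        Retain only points with qlo <= q <= qhi.

    Non-numeric lines (headers etc.) are skipped and counted; points with
    q <= 0 are rejected with a warning; sigma <= 0 entries are replaced by
    a smoothness-based estimate (fitting needs positive weights).
    """
    path = str(path)
    with open(path) as fh:
        rows, skipped, idx = _parse_lines(fh, column_map)
    if not rows:
        raise ValueError(f"empty data set: no parseable data line in {path!r}")

    arr = np.array([r[: max(idx.values()) + 1] for r in rows], dtype=float)
    q = arr[:, idx["q"]]
    I = arr[:, idx["I"]]
    sigma = arr[:, idx["sigma"]] if "sigma" in idx else None

    bad_q = q <= 0
    if bad_q.any():
        warnings.warn(f"{path}: rejected {int(bad_q.sum())} point(s) with q <= 0")
        q, I = q[~bad_q], I[~bad_q]
        if sigma is not None:
            sigma = sigma[~bad_q]
    if q.size == 0:
        raise ValueError(f"empty data set: all points rejected in {path!r}")

    source = tuple(path for _ in q)
    curve = SASCurve(q, I, sigma, source=source)
    curve.log.append(f"read {path}: {q.size} points, {skipped} line(s) skipped")
    curve.skipped_lines = skipped

    if sigma is not None and (sigma <= 0).any():
        n_bad = int((sigma <= 0).sum())
        warnings.warn(f"{path}: {n_bad} point(s) with sigma <= 0 replaced by "
                      "smoothness estimate")
        est = estimate_sigma(curve)
        sigma = np.where(curve.sigma <= 0, est.sigma, curve.sigma)
        curve = curve._derive(curve.q, curve.I, sigma, curve.source,
                              f"replaced {n_bad} nonpositive sigma")
        curve.skipped_lines = skipped

    if q_window is not None:
        sk = curve.skipped_lines
        curve = curve.with_window(*q_window)
        curve.skipped_lines = sk
    return curve


def estimate_sigma(curve: SASCurve, window: int = SIGMA_WINDOW) -> SASCurve:
    """Estimate uncertainties from the smoothness of the curve.

    A quadratic is fitted over a moving window of ``window`` points
    (clipped at the boundaries); the uncertainty of the centre point is the
    rms residual about that local fit.  When all I > 0 the quadratic is
    fitted in (log q, log I) and residuals are taken in linear intensity,
    so that pure power laws leave zero residual.  Curves shorter than the
    window fall back to a single global fit (flag ``sigma_global_fallback``);
    constant curves get a small positive floor.
    """
    q, I = curve.q, curve.I
    n = q.size
    if n == 0:
        raise ValueError("empty data set")
    floor = max(float(np.max(np.abs(I)) if n else 1.0), 1.0) * 1e-12

    loglog = bool(np.all(I > 0) and np.all(q > 0))
    x = np.log(q) if loglog else q

    def local_sigma(sel_lo, sel_hi, at):
        xs = x[sel_lo:sel_hi]
        ys = np.log(I[sel_lo:sel_hi]) if loglog else I[sel_lo:sel_hi]
        m = xs.size
        deg = min(2, m - 1)
        x0 = xs.mean()
        coef = np.polyfit(xs - x0, ys, deg)
        fit = np.polyval(coef, xs - x0)
        resid = I[sel_lo:sel_hi] - np.exp(fit) if loglog else ys - fit
        dof = max(m - (deg + 1), 1)
        return float(np.sqrt(np.sum(resid**2) / dof))

    sigma = np.empty(n)
    flags = set(curve.flags)
    if n < window:
        s = local_sigma(0, n, None) if n >= 2 else floor
        sigma[:] = max(s, floor)
        flags.add("sigma_global_fallback")
        note = f"sigma estimated globally (n={n} < window={window})"
    else:
        half = window // 2
        for i in range(n):
            lo = max(0, min(i - half, n - window))
            sigma[i] = max(local_sigma(lo, lo + window, i), floor)
        note = f"sigma estimated from smoothness (window={window})"

    out = curve._derive(curve.q, curve.I, sigma, curve.source, note)
    out.flags = flags
    return out


def merge_curves(curves, q_windows=None) -> SASCurve:
    """Merge measurements of the same sample spanning different q ranges.

    Per-curve q windows are applied before concatenation; the result is
    sorted by q (duplicates kept as distinct points, ties broken by (I,
    sigma) so the merge is independent of input order).  Provenance per
    point is preserved.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("empty data set: no curves to merge")
    if q_windows is None:
        q_windows = [None] * len(curves)
    if len(q_windows) != len(curves):
        raise ValueError("one q_window (or None) per curve required")

    qs, Is, sigs, srcs, logs = [], [], [], [], []
    have_sigma = all(c.sigma is not None for c in curves)
    for c, win in zip(curves, q_windows):
        if win is not None:
            c = c.with_window(*win)
        qs.append(c.q)
        Is.append(c.I)
        if have_sigma:
            sigs.append(c.sigma)
        srcs.extend(c.source)
        logs.extend(c.log)

    q = np.concatenate(qs)
    if q.size == 0:
        raise ValueError("empty data set after windowing")
    I = np.concatenate(Is)
    sigma = np.concatenate(sigs) if have_sigma else None
    order = np.lexsort((np.zeros_like(q) if sigma is None else sigma, I, q))

    merged = SASCurve(
        q[order], I[order],
        None if sigma is None else sigma[order],
        source=tuple(srcs[i] for i in order),
    )
    merged.log = logs + [f"merged {len(curves)} curve(s): {q.size} points"]
    return merged


def write_curve(curve: SASCurve, path, comment: str = "") -> None:
    """Write 3-column ASCII with a '# '-prefixed comment header.

    Full shortest-repr precision so a read/write round trip is exact.
    """
    with open(str(path), "w") as fh:
        fh.write("# q I sigma\n")
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for entry in curve.log:
            fh.write(f"# log: {entry}\n")
        sig = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
        for qi, Ii, si in zip(curve.q, curve.I, sig):
            fh.write(f"{float(qi)!r} {float(Ii)!r} {float(si)!r}\n")
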