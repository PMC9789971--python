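"""Streamline tractograms in world mm coordinates.

A tractogram is simply a list of polylines (``(n_i, 3)`` float arrays, n_i >=
2) in world mm space — the product of whole-brain fibre tracking on a
normative template. Creating one from diffusion data is upstream of this
package; here we only read, write and resample them. TCK I/O is delegated to
``nibabel.streamlines``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DataContractError

Streamline = np.ndarray  # (n, 3) float, mm
Streamlines = list[Streamline]


def validate_streamlines(streamlines: Streamlines) -> None:
    """Check the tractogram invariants: >=2 vertices, finite, 3-D."""
    for i, sl in enumerate(streamlines):
        sl = np.asarray(sl)
        if sl.ndim != 2 or sl.shape[1] != 3 or sl.shape[0] < 2:
            raise DataContractError(f"streamline {i} is not an (n>=2, 3) polyline")
        if not np.all(np.isfinite(sl)):
            raise DataContractError(f"streamline {i} has non-finite coordinates")


def densify(streamline: Streamline, max_spacing_mm: float) -> Streamline:
    """Resample a polyline so consecutive vertices are <= ``max_spacing_mm`` apart.

    Original vertices are not necessarily retained; the polyline is re-sampled
    at uniform arc-length steps chosen per segment chain, which preserves the
    geometry to within the step size and guarantees the spacing bound. The
    first and last vertices are preserved exactly.
    """
    sl = np.asarray(streamline, dtype=float)
    seg = np.linalg.norm(np.diff(sl, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0.0:
        return sl.copy()
    n_samples = int(np.ceil(total / max_spacing_mm)) + 1
    t = np.linspace(0.0, total, n_samples)
    out = np.column_stack([np.interp(t, arc, sl[:, k]) for k in range(3)])
    return out


def load_tck(path: str | Path) -> Streamlines:
    """Read a TCK file; streamlines come back in world (RAS) mm coordinates."""
    tck = nib.streamlines.load(str(path))
    return [np.asarray(sl, dtype=float) for sl in tck.streamlines]


def save_tck(streamlines: Streamlines, path: str | Path) -> None:
    """Write streamlines (world mm) to TCK."""
    validate_streamlines(streamlines)
    tractogram = nib.streamlines.Tractogram(streamlines, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(path))
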