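"""Streamline file IO (TCK native, TRK with reference geometry).

Streamline coordinates are voxel-centre-based physical μm throughout the
package; that convention is recorded in the written TCK header.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

from .tractography import Streamline

_HEADER_NOTE = "coordinates in voxel-centre physical micrometres (0-based zyx grid)"


def write_streamlines(streamlines: list[Streamline], path: str | Path,
                      reference_affine: np.ndarray | None = None) -> None:
    """Write streamlines as TCK (or TRK when given a reference affine)."""
    path = Path(path)
    tractogram = Tractogram(
        streamlines=[np.asarray(s.points, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.suffix == ".tck":
        f = TckFile(tractogram, header={"comment": _HEADER_NOTE})
        f.save(str(path))
    elif path.suffix == ".trk":
        affine = np.eye(4) if reference_affine is None else reference_affine
        header = {"voxel_to_rasmm": affine}
        TrkFile(tractogram, header=header).save(str(path))
    else:
        raise ValueError(f"unsupported streamline format: {path.suffix}")


def read_streamlines(path: str | Path) -> list[Streamline]:
    """Read a TCK/TRK file back into :class:`Streamline` objects."""
    path = Path(path)
    try:
        tractogram = nib.streamlines.load(str(path)).tractogram
    except Exception as exc:  # nibabel raises assorted header errors
        raise ValueError(f"cannot parse streamline file {path}: {exc}") from exc
    out = []
    for i, pts in enumerate(tractogram.streamlines):
        out.append(Streamline(np.asarray(pts, dtype=float), seed_index=i))
    return out
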