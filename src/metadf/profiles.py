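"""Profile containers shared by the landscape, bias and estimator stages.

A :class:`PMFProfile` is a bulk-referenced free-energy curve A(z); a
:class:`MeanForceProfile` holds binned (optionally bias-weighted) mean
forces along z.  Both round-trip through commented TSV.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .exceptions import BulkReferenceError, EmptyProfileError


@dataclass
class PMFProfile:
    """Potential of mean force A(z), referenced so bulk averages to zero.

    Parameters
    ----------
    z : ndarray
        Grid of separation values (Å), strictly increasing.
    A : ndarray
        Free energy (kJ/mol) on the grid.
    reference_window : tuple of float
        (lo, hi) window (Å) whose mean defines the zero of A.
    provenance : str
        One of ``"exact"``, ``"metadf"``, ``"metad_estimate"`` or a free
        label for user data.
    """

    z: np.ndarray
    A: np.ndarray
    reference_window: tuple
    provenance: str = "user"

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.z.shape != self.A.shape or self.z.ndim != 1:
            raise ValueError("z and A must be matching 1-D arrays")
        if self.z.size and not np.all(np.diff(self.z) > 0):
            raise ValueError("z grid must be strictly increasing")

    def bulk_referenced(self) -> "PMFProfile":
        """Return a copy shifted so the reference-window mean of A is 0."""
        lo, hi = self.reference_window
        mask = (self.z >= lo) & (self.z <= hi)
        if not mask.any():
            raise BulkReferenceError(
                f"no grid points inside reference window [{lo}, {hi}]")
        return PMFProfile(self.z, self.A - self.A[mask].mean(),
                          self.reference_window, self.provenance)

    def bulk_mean(self) -> float:
        lo, hi = self.reference_window
        mask = (self.z >= lo) & (self.z <= hi)
        if not mask.any():
            raise BulkReferenceError(
                f"no grid points inside reference window [{lo}, {hi}]")
        return float(self.A[mask].mean())

    def interp(self, z: np.ndarray) -> np.ndarray:
        """A interpolated at ``z`` (constant extension outside the grid)."""
        return np.interp(np.asarray(z, dtype=float), self.z, self.A)

    # -- TSV I/O -----------------------------------------------------------
    def to_tsv(self, path_or_buf, header_extra: dict | None = None):
        lines = [f"# provenance: {self.provenance}",
                 "# reference_window: "
                 f"{self.reference_window[0]} {self.reference_window[1]}"]
        for k, v in (header_extra or {}).items():
            lines.append(f"# {k}: {v}")
        lines.append("z\tA")
        for zi, ai in zip(self.z, self.A):
            lines.append(f"{zi:.10g}\t{ai:.10g}")
        text = "\n".join(lines) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "PMFProfile":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        provenance = "user"
        window = (-np.inf, np.inf)
        rows = []
        for line in io.StringIO(text):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("provenance:"):
                    provenance = body.split(":", 1)[1].strip()
                elif body.startswith("reference_window:"):
                    parts = body.split(":", 1)[1].split()
                    window = (float(parts[0]), float(parts[1]))
                continue
            if line.startswith("z"):
                continue
            a, b = line.split("\t")
            rows.append((float(a), float(b)))
        arr = np.array(rows)
        if arr.size == 0:
            raise EmptyProfileError("no data rows in PMF TSV")
        return cls(arr[:, 0], arr[:, 1], window, provenance)


@dataclass
class MeanForceProfile:
    """Binned mean force ⟨F⟩(z) along the separation coordinate.

    ``edges`` has ``n_bins + 1`` entries over [r_c, z_wall]; bins with zero
    raw count are flagged empty.  ``ess`` is the Kish effective sample size
    (Σw)²/Σw² per bin and never exceeds the raw count.
    """

    edges: np.ndarray
    mean_force: np.ndarray
    count: np.ndarray
    ess: np.ndarray
    weighting: str = "bias"
    temperature: float = field(default=300.0)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.mean_force = np.asarray(self.mean_force, dtype=float)
        self.count = np.asarray(self.count)
        self.ess = np.asarray(self.ess, dtype=float)
        n = self.edges.size - 1
        if not (self.mean_force.size == self.count.size == self.ess.size == n):
            raise ValueError("inconsistent bin array lengths")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def empty(self) -> np.ndarray:
        return self.count == 0

    def to_tsv(self, path_or_buf, header_extra: dict | None = None):
        lines = [f"# weighting: {self.weighting}",
                 f"# temperature: {self.temperature}"]
        for k, v in (header_extra or {}).items():
            lines.append(f"# {k}: {v}")
        lines.append("z_lo\tz_hi\tmean_force\tcount\tess")
        for i in range(self.mean_force.size):
            lines.append(f"{self.edges[i]:.10g}\t{self.edges[i+1]:.10g}\t"
                         f"{self.mean_force[i]:.10g}\t{self.count[i]:g}\t"
                         f"{self.ess[i]:.10g}")
        text = "\n".join(lines) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)


def pmf_rmse(estimate: PMFProfile, reference: PMFProfile,
             window: tuple) -> float:
    """RMSE between two PMFs over a z-window, on the reference grid.

    The estimate is interpolated onto the reference grid with constant
    extension beyond its support, so a profile that never reached the bulk
    is penalized by its missing offset rather than silently cropped.
    """
    lo, hi = window
    mask = (reference.z >= lo) & (reference.z <= hi)
    if not mask.any():
        raise ValueError("empty comparison window")
    diff = estimate.interp(reference.z[mask]) - reference.A[mask]
    return float(np.sqrt(np.mean(diff ** 2)))
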