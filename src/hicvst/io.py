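"""Reading, writing and converting Hi-C contact matrices.

A contact matrix records interaction counts between genomic bins of one
chromosome pair.  Intra-chromosomal maps are symmetric and stored as the
upper triangle (including the diagonal); inter-chromosomal maps are
rectangular and stored in full.  Two on-disk formats are supported:

* single-resolution ``.cool`` files (the cooler HDF5 schema: ``chroms``,
  ``bins`` and COO ``pixels`` tables), read and written with h5py;
* a sparse triplet TSV with header ``chrom1 start1 chrom2 start2 value``
  and 0-based half-open genomic starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "read_cool",
    "write_cool",
    "read_triplet_tsv",
    "write_triplet_tsv",
    "to_dense",
    "from_dense",
]


class DataError(ValueError):
    """Malformed values in an input file or matrix."""


class ConfigurationError(ValueError):
    """A requested option is unavailable for this input."""


@dataclass
class ContactMatrix:
    """Sparse labeled contact map for one chromosome pair from one replicate.

    Pixels are parallel arrays ``(bin1, bin2, value)`` with 0-based bin
    indices.  For intra-chromosomal matrices only the upper triangle
    (``bin1 <= bin2``) is stored and each bin pair appears at most once.
    """

    chrom1: str
    chrom2: str
    bin_size: int
    n_bins1: int
    n_bins2: int
    bin1: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    bin2: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    value: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def __post_init__(self) -> None:
        self.bin1 = np.asarray(self.bin1, dtype=np.int64)
        self.bin2 = np.asarray(self.bin2, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=float)
        if not (len(self.bin1) == len(self.bin2) == len(self.value)):
            raise ValueError("pixel arrays must have equal length")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.validate()

    # ------------------------------------------------------------------
    @property
    def is_intra(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def n_pixels(self) -> int:
        return len(self.value)

    def validate(self) -> None:
        """Check index-range, finiteness and triangle invariants."""
        if len(self.bin1) == 0:
            return
        if self.bin1.min() < 0 or self.bin1.max() >= self.n_bins1:
            raise DataError("bin1 index out of range")
        if self.bin2.min() < 0 or self.bin2.max() >= self.n_bins2:
            raise DataError("bin2 index out of range")
        if not np.all(np.isfinite(self.value)):
            raise DataError("non-finite pixel value")
        if np.any(self.value < 0):
            raise DataError("negative pixel value")
        if self.is_intra:
            if np.any(self.bin1 > self.bin2):
                raise DataError("intra pixels must satisfy bin1 <= bin2")
            keys = self.bin1 * self.n_bins2 + self.bin2
            if len(np.unique(keys)) != len(keys):
                raise DataError("duplicate intra pixel")

    def sorted_copy(self) -> "ContactMatrix":
        """Return a copy with pixels in (bin1, bin2) lexicographic order."""
        order = np.lexsort((self.bin2, self.bin1))
        return ContactMatrix(
            self.chrom1, self.chrom2, self.bin_size, self.n_bins1, self.n_bins2,
            self.bin1[order], self.bin2[order], self.value[order],
        )

    def with_values(self, values: np.ndarray) -> "ContactMatrix":
        """Copy of this matrix with the pixel values replaced."""
        return ContactMatrix(
            self.chrom1, self.chrom2, self.bin_size, self.n_bins1, self.n_bins2,
            self.bin1.copy(), self.bin2.copy(), np.asarray(values, dtype=float),
        )

    def pixel_set(self) -> set[tuple[int, int, float]]:
        return set(zip(self.bin1.tolist(), self.bin2.tolist(), self.value.tolist()))


def _canonicalize_intra(
    bin1: np.ndarray, bin2: np.ndarray, value: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flip lower-triangle entries above the diagonal; reject mirrored duplicates.

    Silent summation of a pixel given in both triangles would mask malformed
    input, so conflicting mirrors raise instead.
    """
    lo = bin1 > bin2
    b1 = np.where(lo, bin2, bin1)
    b2 = np.where(lo, bin1, bin2)
    keys = b1.astype(np.int64) * n_bins + b2
    uniq, counts = np.unique(keys, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1][0]
        raise DataError(
            f"duplicate intra pixel for bin pair ({dup // n_bins}, {dup % n_bins})"
        )
    return b1, b2, value


# ----------------------------------------------------------------------
# cooler (.cool) single-resolution HDF5 schema
# ----------------------------------------------------------------------

def read_cool(path, chrom1: str, chrom2: str, balanced: bool = False) -> ContactMatrix:
    """Read one chromosome pair from a single-resolution ``.cool`` file.

    Parameters
    ----------
    path
        Path to the cooler file (bins/chroms/pixels layout at the root or
        under ``resolutions/<res>`` is *not* searched: single resolution only).
    chrom1, chrom2
        Chromosome names as stored in the file.
    balanced
        Multiply raw counts by the per-bin ``weight`` column.  Pixels whose
        either weight is NaN (filtered-out bins) are dropped.
    """
    with h5py.File(path, "r") as h5:
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in h5["chroms/name"][:]]
        for c in (chrom1, chrom2):
            if c not in names:
                raise KeyError(f"chromosome {c!r} not present in {path}")
        bin_chrom = h5["bins/chrom"][:]
        bin_start = h5["bins/start"][:]
        # bins/chrom may be an int enum (cooler default) or raw strings
        if np.issubdtype(bin_chrom.dtype, np.integer):
            bin_names = np.array(names)[bin_chrom]
        else:
            bin_names = np.array(
                [n.decode() if isinstance(n, bytes) else str(n) for n in bin_chrom]
            )
        starts = {}
        sizes = {}
        for c in (chrom1, chrom2):
            idx = np.flatnonzero(bin_names == c)
            starts[c] = int(idx[0])
            sizes[c] = int(len(idx))
        bin_size = int(h5.attrs.get("bin-size", 0)) or int(
            bin_start[starts[chrom1] + 1] - bin_start[starts[chrom1]]
            if sizes[chrom1] > 1 else bin_start[1] - bin_start[0]
        )

        p1 = h5["pixels/bin1_id"][:]
        p2 = h5["pixels/bin2_id"][:]
        pv = h5["pixels/count"][:].astype(float)

        lo1, hi1 = starts[chrom1], starts[chrom1] + sizes[chrom1]
        lo2, hi2 = starts[chrom2], starts[chrom2] + sizes[chrom2]
        # cooler stores the upper triangle of the genome-wide map, so the
        # requested pair may appear as (c1, c2) or as (c2, c1) blocks
        sel = (p1 >= lo1) & (p1 < hi1) & (p2 >= lo2) & (p2 < hi2)
        b1 = p1[sel] - lo1
        b2 = p2[sel] - lo2
        vv = pv[sel]
        if chrom1 != chrom2:
            sel_t = (p1 >= lo2) & (p1 < hi2) & (p2 >= lo1) & (p2 < hi1)
            b1 = np.concatenate([b1, p2[sel_t] - lo1])
            b2 = np.concatenate([b2, p1[sel_t] - lo2])
            vv = np.concatenate([vv, pv[sel_t]])

        if balanced:
            if "weight" not in h5["bins"]:
                raise ConfigurationError(
                    "balanced=True requested but the file has no bins/weight column"
                )
            w = h5["bins/weight"][:].astype(float)
            w1 = w[b1 + lo1]
            w2 = w[b2 + lo2]
            keep = np.isfinite(w1) & np.isfinite(w2)
            b1, b2, vv = b1[keep], b2[keep], vv[keep] * w1[keep] * w2[keep]

    if not np.all(np.isfinite(vv)) or np.any(vv < 0):
        raise DataError("negative or non-finite values in cooler pixels")
    if chrom1 == chrom2:
        b1, b2, vv = _canonicalize_intra(b1, b2, vv, sizes[chrom2])
    nz = vv != 0
    m = ContactMatrix(chrom1, chrom2, bin_size, sizes[chrom1], sizes[chrom2],
                      b1[nz], b2[nz], vv[nz])
    return m.sorted_copy()


def write_cool(m: ContactMatrix, path, chrom_sizes: dict[str, int] | None = None,
               weights: np.ndarray | None = None) -> None:
    """Write a contact matrix as a minimal single-resolution ``.cool`` file.

    ``chrom_sizes`` maps chromosome name to length in bp; defaults to
    ``n_bins * bin_size`` for the matrix's own chromosomes.  ``weights``
    optionally stores a per-bin balancing weight vector (concatenated over
    the file's bins) under ``bins/weight``.
    """
    if chrom_sizes is None:
        chrom_sizes = {m.chrom1: m.n_bins1 * m.bin_size}
        if not m.is_intra:
            chrom_sizes[m.chrom2] = m.n_bins2 * m.bin_size
    names = list(chrom_sizes)
    name_idx = {c: i for i, c in enumerate(names)}
    bin_chrom, bin_start, bin_end = [], [], []
    offsets = {}
    for c in names:
        nb = int(np.ceil(chrom_sizes[c] / m.bin_size))
        offsets[c] = len(bin_chrom)
        for k in range(nb):
            bin_chrom.append(name_idx[c])
            bin_start.append(k * m.bin_size)
            bin_end.append(min((k + 1) * m.bin_size, chrom_sizes[c]))

    b1 = m.bin1 + offsets[m.chrom1]
    b2 = m.bin2 + offsets[m.chrom2]
    # genome-wide upper triangle convention
    flip = b1 > b2
    b1, b2 = np.where(flip, b2, b1), np.where(flip, b1, b2)
    order = np.lexsort((b2, b1))

    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "HDF5::Cooler"
        h5.attrs["format-version"] = 3
        h5.attrs["bin-size"] = m.bin_size
        h5.attrs["bin-type"] = "fixed"
        h5.attrs["symmetric-upper"] = True
        g = h5.create_group("chroms")
        g.create_dataset("name", data=np.array(names, dtype="S32"))
        g.create_dataset("length", data=np.array([chrom_sizes[c] for c in names],
                                                 dtype=np.int64))
        g = h5.create_group("bins")
        g.create_dataset("chrom", data=np.array(bin_chrom, dtype=np.int32))
        g.create_dataset("start", data=np.array(bin_start, dtype=np.int64))
        g.create_dataset("end", data=np.array(bin_end, dtype=np.int64))
        if weights is not None:
            g.create_dataset("weight", data=np.asarray(weights, dtype=float))
        g = h5.create_group("pixels")
        g.create_dataset("bin1_id", data=b1[order].astype(np.int64))
        g.create_dataset("bin2_id", data=b2[order].astype(np.int64))
        g.create_dataset("count", data=m.value[order])


# ----------------------------------------------------------------------
# sparse triplet TSV
# ----------------------------------------------------------------------

_TSV_COLS = ["chrom1", "start1", "chrom2", "start2", "value"]


def read_triplet_tsv(path, bin_size: int,
                     n_bins1: int | None = None,
                     n_bins2: int | None = None) -> ContactMatrix:
    """Read a sparse triplet TSV (``chrom1 start1 chrom2 start2 value``).

    Starts are 0-based, half-open and must be multiples of ``bin_size``.
    Matrix dimensions default to the largest bin index seen plus one.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TSV_COLS if c not in df.columns]
    if missing:
        raise DataError(f"triplet TSV missing columns {missing}")
    if len(df) == 0:
        raise DataError("empty triplet TSV")
    c1 = str(df["chrom1"].iloc[0])
    c2 = str(df["chrom2"].iloc[0])
    if not (df["chrom1"] == c1).all() or not (df["chrom2"] == c2).all():
        raise DataError("triplet TSV must contain a single chromosome pair")
    s1 = df["start1"].to_numpy(dtype=np.int64)
    s2 = df["start2"].to_numpy(dtype=np.int64)
    if np.any(s1 % bin_size) or np.any(s2 % bin_size):
        raise DataError(f"start coordinates are not multiples of bin_size={bin_size}")
    b1 = s1 // bin_size
    b2 = s2 // bin_size
    vv = df["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vv)) or np.any(vv < 0):
        raise DataError("negative or non-finite values in triplet TSV")
    n1 = n_bins1 if n_bins1 is not None else int(b1.max()) + 1
    n2 = n_bins2 if n_bins2 is not None else int(b2.max()) + 1
    if c1 == c2:
        n1 = n2 = max(n1, n2)
        b1, b2, vv = _canonicalize_intra(b1, b2, vv, n2)
    return ContactMatrix(c1, c2, bin_size, n1, n2, b1, b2, vv).sorted_copy()


def write_triplet_tsv(m: ContactMatrix, path) -> None:
    """Write pixels as a canonically sorted triplet TSV."""
    ms = m.sorted_copy()
    df = pd.DataFrame({
        "chrom1": ms.chrom1,
        "start1": ms.bin1 * ms.bin_size,
        "chrom2": ms.chrom2,
        "start2": ms.bin2 * ms.bin_size,
        "value": ms.value,
    })
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# dense conversion
# ----------------------------------------------------------------------

def to_dense(m: ContactMatrix) -> np.ndarray:
    """Densify to an ``n_bins1 x n_bins2`` array; intra maps are mirrored."""
    a = np.zeros((m.n_bins1, m.n_bins2))
    a[m.bin1, m.bin2] = m.value
    if m.is_intra:
        off = m.bin1 != m.bin2
        a[m.bin2[off], m.bin1[off]] = m.value[off]
    return a


def from_dense(a: np.ndarray, chrom1: str, chrom2: str, bin_size: int,
               tol: float = 0.0) -> ContactMatrix:
    """Build a sparse contact matrix from a dense array.

    Intra input must be symmetric to within ``tol``; only the upper triangle
    is kept. Zeros are dropped.
    """
    a = np.asarray(a, dtype=float)
    if chrom1 == chrom2:
        if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=tol):
            raise DataError("intra-chromosomal dense matrix must be symmetric")
        iu = np.triu_indices(a.shape[0])
        b1, b2 = iu
        vv = a[iu]
    else:
        b1, b2 = np.indices(a.shape).reshape(2, -1)
        vv = a.ravel()
    nz = vv != 0
    return ContactMatrix(chrom1, chrom2, bin_size, a.shape[0], a.shape[1],
                         b1[nz], b2[nz], vv[nz])
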