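"""Graph construction for EEG montages and audio slice sequences.

The EEG graph combines two binary edge sets on the projected 2-D montage:
local edges from k-nearest-neighbor spatial proximity, and inter-hemispheric
edges joining left/right symmetric electrode pairs (hemispheric asymmetry of
resting EEG is informative for depression, so the network is given explicit
cross-hemisphere message-passing routes).  The audio graph is a temporal
chain over equal-length slices: nodes j and k are connected iff |j - k| = 1.

Adjacency matrices are plain dense ``{0,1}`` numpy arrays with zero diagonal;
self-loops are added inside the convolution, never stored here.  Node order
is the montage row order, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeMontage",
    "build_local_adjacency",
    "build_symmetric_adjacency",
    "combine_adjacency",
    "build_chain_adjacency",
    "default_symmetric_pairs",
    "validate_adjacency",
    "read_montage",
    "write_montage",
    "read_symmetric_pairs",
    "write_symmetric_pairs",
    "write_adjacency",
    "read_adjacency",
]

_HEMISPHERES = frozenset({"left", "right", "midline"})


@dataclass(frozen=True)
class ElectrodeMontage:
    """Electrode labels with 2-D projected scalp coordinates.

    Parameters
    ----------
    labels : list of str
        Unique channel identifiers; row order defines node order.
    coords : (n, 2) array
        Unitless positions on the projected scalp plane.
    hemisphere : list of str
        Per-channel tag, one of ``left`` / ``right`` / ``midline``.
    """

    labels: tuple
    coords: np.ndarray
    hemisphere: tuple

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "hemisphere", tuple(self.hemisphere))
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("montage labels must be unique")
        if coords.shape != (n, 2):
            raise ValueError(f"coords must be ({n}, 2), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("montage coordinates must be finite")
        if len(self.hemisphere) != n:
            raise ValueError("hemisphere tags must match label count")
        bad = set(self.hemisphere) - _HEMISPHERES
        if bad:
            raise ValueError(f"unknown hemisphere tags: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel label not in montage: {label!r}") from None


def validate_adjacency(a: np.ndarray, *, name: str = "adjacency") -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    if not np.array_equal(a, a.T):
        raise ValueError(f"{name} must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError(f"{name} must have a zero diagonal")
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} entries must be binary")
    return a


def build_local_adjacency(montage: ElectrodeMontage, k: int = 4) -> np.ndarray:
    """k-nearest-neighbor adjacency on the 2-D montage coordinates.

    Each channel is linked to its ``k`` nearest neighbors by Euclidean
    distance; the result is symmetrized (an edge is kept if either endpoint
    selected it).  Distance ties are broken by lower channel index, so the
    construction is deterministic for duplicate coordinates.
    """
    n = montage.n_channels
    if not 0 < k < n:
        raise ValueError(f"k must satisfy 0 < k < n_channels={n}, got {k}")
    diff = montage.coords[:, None, :] - montage.coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    a = np.zeros((n, n), dtype=np.int8)
    # stable argsort -> lower index wins distance ties
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    a[rows, order.ravel()] = 1
    a = np.maximum(a, a.T)
    return a


def build_symmetric_adjacency(montage: ElectrodeMontage,
                              pairs: list[tuple[str, str]]) -> np.ndarray:
    """Adjacency holding exactly the listed left/right electrode pairs."""
    n = montage.n_channels
    a = np.zeros((n, n), dtype=np.int8)
    seen = set()
    for left_label, right_label in pairs:
        i = montage.index_of(left_label)
        j = montage.index_of(right_label)
        if montage.hemisphere[i] != "left" or montage.hemisphere[j] != "right":
            raise ValueError(
                f"pair ({left_label!r}, {right_label!r}) must join a left-"
                f"hemisphere channel to a right-hemisphere channel, got "
                f"({montage.hemisphere[i]}, {montage.hemisphere[j]})")
        if (i, j) in seen:
            raise ValueError(f"duplicate symmetric pair ({left_label!r}, {right_label!r})")
        seen.add((i, j))
        a[i, j] = 1
        a[j, i] = 1
    return a


def combine_adjacency(a_init: np.ndarray, a_sym: np.ndarray) -> np.ndarray:
    """Union of two binary edge sets: elementwise sum clipped to {0, 1}.

    Downstream normalization expects a connectivity pattern, not edge
    multiplicities, so an edge present in both inputs stays a single edge.
    """
    a_init = np.asarray(a_init)
    a_sym = np.asarray(a_sym)
    if a_init.shape != a_sym.shape:
        raise ValueError(
            f"adjacency shapes differ: {a_init.shape} vs {a_sym.shape}")
    return np.minimum(a_init + a_sym, 1).astype(np.int8)


def build_chain_adjacency(n: int) -> np.ndarray:
    """Temporal chain over ``n`` audio slices: A(j,k)=1 iff |j-k|=1."""
    if n <= 0:
        raise ValueError(f"slice count must be positive, got {n}")
    a = np.zeros((n, n), dtype=np.int8)
    idx = np.arange(n - 1)
    a[idx, idx + 1] = 1
    a[idx + 1, idx] = 1
    return a


def default_symmetric_pairs(montage: ElectrodeMontage) -> list[tuple[str, str]]:
    """Mirror-match each left channel to its closest right counterpart.

    For every left-hemisphere channel at (x, y), find the right-hemisphere
    channel nearest to the mirror image (-x, y).  Each right channel is used
    at most once (greedy by mirror distance, ties by lower left index).
    """
    left = [i for i, h in enumerate(montage.hemisphere) if h == "left"]
    right = [i for i, h in enumerate(montage.hemisphere) if h == "right"]
    if not left or not right:
        return []
    mirrored = montage.coords[left] * np.array([-1.0, 1.0])
    d = np.sqrt(((mirrored[:, None, :] - montage.coords[right][None, :, :]) ** 2).sum(-1))
    # greedy assignment in order of ascending mirror distance
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None, kind="stable"),
                                       d.shape))[0]
    used_left, used_right = set(), set()
    pairs: list[tuple[str, str]] = []
    for li, ri in order:
        if li in used_left or ri in used_right:
            continue
        used_left.add(li)
        used_right.add(ri)
        pairs.append((montage.labels[left[li]], montage.labels[right[ri]]))
    pairs.sort(key=lambda p: montage.index_of(p[0]))
    return pairs


# -- file formats ----------------------------------------------------------

def read_montage(path) -> ElectrodeMontage:
    """Read a montage table (CSV/TSV with columns label,x,y,hemisphere)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"label", "x", "y", "hemisphere"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"montage file missing columns: {sorted(missing)}")
    return ElectrodeMontage(
        labels=[str(v) for v in df["label"]],
        coords=df[["x", "y"]].to_numpy(dtype=float),
        hemisphere=[str(v) for v in df["hemisphere"]],
    )


def write_montage(montage: ElectrodeMontage, path) -> None:
    pd.DataFrame({
        "label": montage.labels,
        "x": montage.coords[:, 0],
        "y": montage.coords[:, 1],
        "hemisphere": montage.hemisphere,
    }).to_csv(path, index=False)


def read_symmetric_pairs(path) -> list[tuple[str, str]]:
    """Two-column CSV of left_label,right_label."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("symmetric-pair file needs two columns")
    return [(str(a), str(b)) for a, b in df.iloc[:, :2].itertuples(index=False)]


def write_symmetric_pairs(pairs: list[tuple[str, str]], path) -> None:
    pd.DataFrame(pairs, columns=["left_label", "right_label"]).to_csv(path, index=False)


def write_adjacency(a: np.ndarray, path, dense_path=None) -> None:
    """Write an edge-list TSV (i, j, 1 with i < j); optional dense CSV."""
    a = validate_adjacency(a)
    i, j = np.nonzero(np.triu(a, k=1))
    pd.DataFrame({"i": i, "j": j, "w": np.ones(len(i), dtype=int)}).to_csv(
        path, sep="\t", index=False)
    if dense_path is not None:
        np.savetxt(dense_path, a, fmt="%d", delimiter=",")


def read_adjacency(path, n: int) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    a = np.zeros((n, n), dtype=np.int8)
    ii = df["i"].to_numpy(int)
    jj = df["j"].to_numpy(int)
    if len(ii) and (ii.min() < 0 or jj.max() >= n):
        raise ValueError("edge index out of range for requested node count")
    a[ii, jj] = 1
    a[jj, ii] = 1
    return a
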