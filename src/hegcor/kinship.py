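"""Pairwise relatedness and pseudomarker interpolation.

Kinship here is the probability that an allele sampled from individual i
matches one sampled from j.  Two substrates are supported:

* biallelic dosages — the standardized-genotype cross-product averaged over
  markers and divided by 2, matching the convention of founder-probability
  kinship in highly heterozygous outbred populations;
* founder-haplotype probabilities — the average over markers of
  sum_f P(i carries f) * P(j carries f).

Founder probabilities from different genotyping arrays are made comparable
by linear interpolation onto a common pseudomarker grid.
"""

from __future__ import annotations

import dataclasses
import logging

import h5py
import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FounderProbs",
    "KinshipMatrix",
    "PseudomarkerGrid",
    "kinship_from_genotypes",
    "kinship_from_founder_probs",
    "interpolate_probs",
    "read_founder_probs_hdf5",
    "write_founder_probs_hdf5",
    "read_kinship_csv",
    "write_kinship_csv",
]


@dataclasses.dataclass
class FounderProbs:
    """Founder-haplotype probabilities: individuals x markers x founders."""

    probs: np.ndarray
    marker_map: pd.DataFrame  # columns: marker, chromosome, position
    founder_labels: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        if self.probs.ndim != 3:
            raise ValueError("probs must be 3-D (individuals x markers x founders)")
        if len(self.marker_map) != self.probs.shape[1]:
            raise ValueError("one marker-map row required per marker")
        if np.any(self.probs < -1e-9):
            raise ValueError("founder probabilities must be non-negative")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("founder probabilities must sum to 1 per (individual, marker)")

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    @property
    def n_markers(self) -> int:
        return self.probs.shape[1]

    @property
    def n_founders(self) -> int:
        return self.probs.shape[2]


@dataclasses.dataclass
class KinshipMatrix:
    """Symmetric matrix of pairwise allele-sharing probabilities."""

    values: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kinship must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("kinship contains non-finite entries")
        n = v.shape[0]
        if n <= 600:
            sym = np.allclose(v, v.T, atol=1e-10)
        else:
            # spot-check symmetry on a deterministic submatrix; full n^2
            # comparison is wasteful for large cohorts
            idx = np.linspace(0, n - 1, 512).astype(int)
            sub = v[np.ix_(idx, idx)]
            sym = np.allclose(sub, sub.T, atol=1e-10)
        if not sym:
            raise ValueError("kinship must be symmetric")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    def index_of(self, ids) -> np.ndarray:
        lookup = {str(i): k for k, i in enumerate(self.ids)}
        try:
            return np.array([lookup[str(i)] for i in ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"individual {exc} absent from kinship matrix") from exc


@dataclasses.dataclass
class PseudomarkerGrid:
    """Ordered pseudomarker positions, one array per chromosome."""

    positions: dict  # chromosome -> strictly increasing positions (Mb)

    def __post_init__(self) -> None:
        for c, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.ndim != 1 or np.any(np.diff(pos) <= 0):
                raise ValueError(f"grid positions for chromosome {c} must be strictly increasing")
            self.positions[c] = pos


def kinship_from_genotypes(G: GenotypeMatrix) -> KinshipMatrix:
    """Standardized-genotype cross-product kinship, divided by 2.

    K = Z Z' / (2 M) with Z the dosages standardized by the empirical allele
    frequency of each marker.  Monomorphic markers carry no information about
    relatedness and are dropped (with a warning); an input with no polymorphic
    marker is rejected.
    """
    X = G.dosages.astype(float)
    if X.shape[0] < 2:
        raise ValueError("kinship requires at least two individuals")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not np.any(poly):
        raise ValueError("no polymorphic markers: kinship undefined")
    if not np.all(poly):
        logger.warning("dropping %d monomorphic markers from kinship", int((~poly).sum()))
    X = X[:, poly]
    p = p[poly]
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    K = (Z @ Z.T) / (2.0 * Z.shape[1])
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, np.asarray(G.ids))


def kinship_from_founder_probs(P: FounderProbs) -> KinshipMatrix:
    """Allele-sharing kinship from founder probabilities.

    K_ij = mean over markers of sum_f probs[i,m,f] * probs[j,m,f]; the
    diagonal is computed by the same formula.  Entries lie in [0, 1].
    """
    n, m, f = P.probs.shape
    flat = P.probs.reshape(n, m * f)
    K = (flat @ flat.T) / m
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, np.asarray(P.ids))


def interpolate_probs(P: FounderProbs, grid: PseudomarkerGrid) -> FounderProbs:
    """Linearly interpolate founder probabilities onto a pseudomarker grid.

    Interpolation is per founder in physical position between the flanking
    markers; pseudomarkers outside the observed range clamp to the nearest
    marker.  The result is renormalized so each probability vector sums to 1.
    """
    chroms_in = set(P.marker_map["chromosome"].unique())
    missing = set(grid.positions) - chroms_in
    if missing:
        raise ValueError(f"grid chromosomes {sorted(missing)} absent from input")

    blocks, map_rows = [], []
    for c in sorted(grid.positions):
        sel = (P.marker_map["chromosome"] == c).to_numpy()
        if not sel.any():
            raise ValueError(f"chromosome {c} has no markers")
        pos = P.marker_map.loc[sel, "position"].to_numpy(dtype=float)
        order = np.argsort(pos)
        pos = pos[order]
        sub = P.probs[:, sel, :][:, order, :]
        gpos = grid.positions[c]
        # flanking indices and linear weights, end-clamped
        hi = np.clip(np.searchsorted(pos, gpos, side="left"), 0, len(pos) - 1)
        lo = np.clip(hi - 1, 0, len(pos) - 1)
        denom = pos[hi] - pos[lo]
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(denom > 0, (gpos - pos[lo]) / np.where(denom == 0, 1.0, denom), 0.0)
        w = np.clip(w, 0.0, 1.0)
        out = sub[:, lo, :] * (1.0 - w)[None, :, None] + sub[:, hi, :] * w[None, :, None]
        out /= out.sum(axis=2, keepdims=True)
        blocks.append(out)
        map_rows.append(pd.DataFrame({
            "marker": [f"c{c}_p{int(round(p * 1e6))}" for p in gpos],
            "chromosome": c,
            "position": gpos,
        }))
    probs = np.concatenate(blocks, axis=1)
    return FounderProbs(probs, pd.concat(map_rows, ignore_index=True), P.founder_labels, P.ids)


# ---------------------------------------------------------------------------
# IO

def write_founder_probs_hdf5(P: FounderProbs, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("ids", data=np.asarray(P.ids, dtype="S"))
        f.create_dataset("founders", data=np.asarray(P.founder_labels, dtype="S"))
        for c in P.marker_map["chromosome"].unique():
            sel = (P.marker_map["chromosome"] == c).to_numpy()
            f.create_dataset(f"probs/chr{c}", data=P.probs[:, sel, :], chunks=True)
            grp = f.create_group(f"map/chr{c}")
            grp.create_dataset("position", data=P.marker_map.loc[sel, "position"].to_numpy())
            grp.create_dataset("marker", data=P.marker_map.loc[sel, "marker"].to_numpy(dtype="S"))


def read_founder_probs_hdf5(path) -> FounderProbs:
    with h5py.File(path, "r") as f:
        ids = f["ids"][...].astype(str)
        founders = f["founders"][...].astype(str)
        blocks, rows = [], []
        chroms = sorted(f["probs"], key=lambda s: (len(s), s))
        for cname in chroms:
            blocks.append(f[f"probs/{cname}"][...])
            c = cname.removeprefix("chr")
            c = int(c) if c.isdigit() else c
            rows.append(pd.DataFrame({
                "marker": f[f"map/{cname}/marker"][...].astype(str),
                "chromosome": c,
                "position": f[f"map/{cname}/position"][...],
            }))
    return FounderProbs(np.concatenate(blocks, axis=1), pd.concat(rows, ignore_index=True), founders, ids)


def write_kinship_csv(K: KinshipMatrix, path) -> None:
    pd.DataFrame(K.values, index=pd.Index(K.ids, name="id"), columns=K.ids).to_csv(path)


def read_kinship_csv(path) -> KinshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return KinshipMatrix(df.to_numpy(dtype=float), df.index.to_numpy(dtype=str))
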