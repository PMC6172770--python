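"""Community-ecology statistics over the vOTU abundance/detection matrix.

Diversity (richness, Shannon H', Pielou J), Bray-Curtis dissimilarity,
principal-coordinate analysis, randomized collector curves, habitat
sharing (Euler regions), codon-usage profiles, and a contaminant screen.
Shannon entropy uses natural log by default (so Pielou is H'/ln richness);
PCoA handles negative eigenvalues by exclusion-and-report.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .dereplicate import compute_ani

_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


@dataclass
class DiversityResult:
    richness: int
    shannon: float  # H', nats by default
    pielou: float  # J = H' / ln(richness); 0 when richness <= 1


def diversity(abundance_row: Sequence[float] | pd.Series, base: float = np.e) -> DiversityResult:
    """Richness, Shannon H' and Pielou J of one sample.

    Computed on the total-sum-scaled positive values; zeros contribute
    nothing.  ``base`` switches the entropy logarithm (default natural).
    """
    p = np.asarray(abundance_row, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    p = p[p > 0]
    richness = int(p.size)
    if richness == 0:
        return DiversityResult(0, 0.0, 0.0)
    p = p / p.sum()
    h = float(-(p * (np.log(p) / np.log(base))).sum())
    j = float(h / (np.log(richness) / np.log(base))) if richness >= 2 else 0.0
    return DiversityResult(richness, h, j)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample rows.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); pairs of all-zero rows are
    defined as 0 with a warning.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    zero_rows = X.sum(axis=1) == 0
    with np.errstate(invalid="ignore"):
        D = squareform(pdist(X, metric="braycurtis"))
    if np.isnan(D).any():
        if zero_rows.sum() >= 2:
            warnings.warn("all-zero sample pairs: Bray-Curtis defined as 0")
        D = np.nan_to_num(D, nan=0.0)
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def pcoa(dissimilarity: pd.DataFrame | np.ndarray) -> OrdinationResult:
    """Classical metric scaling of a dissimilarity matrix.

    Double-centres -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their eigenvalues.  Axes are ordered by eigenvalue;
    the sign convention makes the first nonzero loading of each axis
    positive.  Negative eigenvalues (non-Euclidean input) are excluded
    from the coordinates and the variance numerator but reported, so the
    explained fractions sum to <= 1.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        index = dissimilarity.index
        D = dissimilarity.to_numpy(dtype=float)
    else:
        D = np.asarray(dissimilarity, dtype=float)
        index = pd.RangeIndex(D.shape[0])
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-10):
        raise ValueError("dissimilarity must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-10 * abs(vals).max()) if n else 0.0
    pos = vals > tol
    neg = vals < -tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    for a in range(coords.shape[1]):
        nz = np.nonzero(np.abs(coords[:, a]) > 1e-12)[0]
        if nz.size and coords[nz[0], a] < 0:
            coords[:, a] *= -1
    denom = vals[pos].sum() + np.abs(vals[neg]).sum()
    prop = vals[pos] / denom if denom > 0 else vals[pos]
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=index, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=vals[pos],
        proportion_explained=prop,
        negative_eigenvalues=vals[neg],
    )


@dataclass
class CollectorCurve:
    mean: np.ndarray  # mean cumulative richness per added sample
    curves: np.ndarray  # n_randomizations x n_samples


def collectors_curve(
    presence: pd.DataFrame | np.ndarray, n_randomizations: int = 50, seed: int = 0
) -> CollectorCurve:
    """Cumulative distinct-taxon counts over randomised sample orders."""
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    P = np.asarray(presence, dtype=bool)
    rng = np.random.default_rng(seed)
    n = P.shape[0]
    curves = np.empty((n_randomizations, n), dtype=int)
    for r in range(n_randomizations):
        order = rng.permutation(n)
        seen = np.logical_or.accumulate(P[order], axis=0)
        curves[r] = seen.sum(axis=1)
    return CollectorCurve(mean=curves.mean(axis=0), curves=curves)


@dataclass
class HabitatSharing:
    per_habitat: dict[str, set[str]]  # habitat -> detected taxa
    pairwise_shared: pd.DataFrame  # habitat x habitat shared counts
    regions: dict[frozenset[str], int]  # Euler region (habitat combo) -> taxon count
    multi_habitat_fraction: float  # fraction of detected taxa in > 1 habitat


def habitat_sharing(
    presence: pd.DataFrame, habitat_labels: Mapping[str, str]
) -> HabitatSharing:
    """Habitat-level presence sets, pairwise sharing, and Euler regions.

    ``presence`` is samples x taxa booleans; each sample must carry a
    habitat label.  Euler region sizes partition the detected taxa and are
    consistent with inclusion-exclusion by construction.
    """
    for s in presence.index:
        if s not in habitat_labels:
            raise ValueError(f"sample {s!r} has no habitat label")
    habitats = sorted(set(habitat_labels[s] for s in presence.index))
    per_habitat: dict[str, set[str]] = {h: set() for h in habitats}
    for s in presence.index:
        h = habitat_labels[s]
        per_habitat[h] |= set(presence.columns[presence.loc[s].astype(bool)])

    shared = pd.DataFrame(0, index=habitats, columns=habitats)
    for a in habitats:
        for b in habitats:
            shared.loc[a, b] = len(per_habitat[a] & per_habitat[b])

    detected = set().union(*per_habitat.values()) if habitats else set()
    regions: dict[frozenset[str], int] = {}
    for taxon in detected:
        combo = frozenset(h for h in habitats if taxon in per_habitat[h])
        regions[combo] = regions.get(combo, 0) + 1
    multi = sum(n for combo, n in regions.items() if len(combo) > 1)
    frac = multi / len(detected) if detected else 0.0
    return HabitatSharing(
        per_habitat=per_habitat,
        pairwise_shared=shared,
        regions=regions,
        multi_habitat_fraction=frac,
    )


def codon_usage_profile(cds_sequences: Mapping[str, str] | Iterable[str]) -> pd.Series:
    """64-component codon frequency vector over all CDSs pooled.

    Every CDS length must be divisible by 3; codons containing characters
    outside A/C/G/T (e.g. N) are skipped.  The vector sums to 1.
    """
    if isinstance(cds_sequences, Mapping):
        items = list(cds_sequences.items())
    else:
        items = [(f"cds{i + 1}", s) for i, s in enumerate(cds_sequences)]
    counts = dict.fromkeys(_CODONS, 0)
    total = 0
    for name, seq in items:
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS {name!r} length {len(seq)} is not divisible by 3")
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
                total += 1
    freq = pd.Series(counts, dtype=float)
    if total:
        freq /= total
    return freq


def screen_contaminants(
    contigs: Mapping[str, str],
    reference_set: Mapping[str, str],
    min_ani: float = 0.95,
    min_aligned_len: int = 500,
) -> list[str]:
    """Flag contigs matching any reference above ``min_ani``.

    A contig is flagged when its best qualifying alignment (at least
    ``min_aligned_len`` columns, so incidental short word hits cannot flag
    a contig) to any reference exceeds the ANI threshold.  Removal is the
    caller's choice.  An empty reference set flags nothing.
    """
    flagged = []
    for cid in sorted(contigs):
        for ref in sorted(reference_set):
            res = compute_ani(contigs[cid], reference_set[ref])
            if res.aligned_len >= min_aligned_len and res.ani > min_ani:
                flagged.append(cid)
                break
    return flagged


def habitat_fold_factors(
    abundance: pd.DataFrame,
    habitat_labels: Mapping[str, str],
    reference_habitat: str,
    contig_lengths: Mapping[str, int] | None = None,
) -> pd.Series:
    """Per-habitat total detected abundance relative to a reference habitat.

    Each sample's detected abundances (per-Gbp scale) are summed, samples
    are averaged within habitat, and habitats are expressed as fold factors
    over the reference -- the measured counterpart of an abundance gradient
    along the thaw sequence.  When ``contig_lengths`` is given the sum is
    length-weighted, i.e. the mapped viral bp share of each library; this
    makes the estimate invariant to the genome-length composition of each
    habitat's pool (an unweighted per-Gbp sum weights populations by
    1/length, so pools that happen to hold shorter genomes look more
    abundant).
    """
    if contig_lengths is not None:
        weights = pd.Series({c: float(contig_lengths[c]) for c in abundance.columns})
        totals = (abundance * weights).sum(axis=1)
    else:
        totals = abundance.sum(axis=1)
    by_hab = totals.groupby(pd.Series({s: habitat_labels[s] for s in abundance.index})).mean()
    if reference_habitat not in by_hab.index:
        raise ValueError(f"reference habitat {reference_habitat!r} has no samples")
    return by_hab / by_hab[reference_habitat]
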