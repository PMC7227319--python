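"""Candidate feature selection for per-locus methylation models.

For every model locus (EPIC-only CpG) three candidate predictor loci
are identified among the feature loci (CpGs on both 450K and EPIC):

* the **co-methylated locus** — the feature locus whose cross-sample
  beta vector is maximally Pearson-correlated with the model locus;
* the **nearest neighbouring locus** on the same chromosome;
* the **most similar flanking-sequence locus** — maximal Pearson
  correlation between 340-dimensional k-mer frequency vectors (all
  1- to 4-mers of the 200-bp flanking window).

All argmax selections are deterministic: ties break by smallest
genomic distance (when a manifest is supplied), then lexicographically
smallest probe ID.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrays_io import GenomeSequences, MethylationMatrix, ProbeManifest, fetch_flank

logger = logging.getLogger(__name__)

#: floor on pairwise-complete sample count for a correlation to be eligible
DEFAULT_MIN_SAMPLES = 30

KMER_KS = (1, 2, 3, 4)

#: all 1..4-mers in lexicographic order within each k-block: 4+16+64+256 = 340
KMER_ORDER: tuple[str, ...] = tuple(
    "".join(t) for k in KMER_KS for t in itertools.product("ACGT", repeat=k)
)

N_KMER_FEATURES = len(KMER_ORDER)

_KMER_INDEX = {kmer: i for i, kmer in enumerate(KMER_ORDER)}
_BLOCK_SLICES = {}
_off = 0
for _k in KMER_KS:
    _BLOCK_SLICES[_k] = slice(_off, _off + 4**_k)
    _off += 4**_k
del _off, _k


def kmer_features(flank_sequence: str) -> np.ndarray:
    """340-vector of k-mer occurrence frequencies (k = 1..4).

    Windows slide by 1; any window containing a base outside {A,C,G,T}
    (e.g. N) is skipped.  Within each k-block frequencies are counts
    divided by the number of valid windows of that k, so each block
    sums to 1, or is all zero when no valid window exists.
    """
    seq = flank_sequence.upper()
    vec = np.zeros(N_KMER_FEATURES)
    if not seq:
        logger.warning("empty flanking sequence; returning all-zero feature vector")
        return vec
    for k in KMER_KS:
        block = _BLOCK_SLICES[k]
        counts = np.zeros(4**k)
        total = 0
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            idx = _KMER_INDEX.get(kmer)
            if idx is None:  # contains N or other non-ACGT base
                continue
            counts[idx - block.start] += 1
            total += 1
        if total:
            vec[block] = counts / total
    return vec


def _pearson_masked(y: np.ndarray, F: np.ndarray, min_samples: int = 2):
    """Pairwise-complete Pearson r of ``y`` (n,) against each row of ``F`` (m, n).

    Returns ``(r, n_used)``; r is NaN where fewer than ``min_samples``
    complete pairs exist or either vector is constant on the overlap.
    """
    y = np.asarray(y, dtype=float)
    F = np.atleast_2d(np.asarray(F, dtype=float))
    mask = ~np.isnan(y)[None, :] & ~np.isnan(F)
    n = mask.sum(axis=1)
    yv = np.where(mask, y[None, :], 0.0)
    fv = np.where(mask, F, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sy = yv.sum(axis=1)
        sf = fv.sum(axis=1)
        cov = (yv * fv).sum(axis=1) - sy * sf / n
        vy = (yv * yv).sum(axis=1) - sy * sy / n
        vf = (fv * fv).sum(axis=1) - sf * sf / n
        r = cov / np.sqrt(vy * vf)
    # numerical guard: constants give vy/vf ~ 0 possibly slightly negative
    bad = (n < max(min_samples, 2)) | ~(vy > 0) | ~(vf > 0)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    return r, n


def pearson_methylation(
    a: np.ndarray, b: np.ndarray, min_samples: int = 2
) -> tuple[float, int]:
    """Pearson correlation of two beta vectors over pairwise-complete samples.

    Returns ``(r, n_used)``; r is NaN (flagged undefined) when fewer
    than ``min_samples`` complete pairs remain or either vector has
    zero variance on the overlap.
    """
    r, n = _pearson_masked(np.asarray(a, float), np.asarray(b, float)[None, :], min_samples)
    return float(r[0]), int(n[0])


def pearson_sequence(s1: np.ndarray, s2: np.ndarray) -> float:
    """Pearson correlation between two 340-component k-mer feature vectors."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != (N_KMER_FEATURES,) or s2.shape != (N_KMER_FEATURES,):
        raise ValueError(f"expected length-{N_KMER_FEATURES} feature vectors")
    r, _ = _pearson_masked(s1, s2[None, :], min_samples=2)
    return float(r[0])


@dataclass
class FeatureAssignment:
    """The selected candidate features of one model locus."""

    model_probe_id: str
    comethylated: tuple[str, float] | None = None
    n_overlapping_samples: int = 0
    nearest: tuple[str, int] | None = None
    sequence_match: tuple[str, float] | None = None

    def feature_probes(self, mode: str = "cometh") -> list[str]:
        """Ordered feature probes for a fitting mode.

        Modes: ``cometh`` (co-methylated only), ``cometh+nn`` (adds the
        nearest neighbour), ``cometh+nn+seq`` (adds the sequence match).
        Features that were not assignable are simply absent.
        """
        probes = []
        if self.comethylated is not None:
            probes.append(self.comethylated[0])
        if mode in ("cometh+nn", "cometh+nn+seq") and self.nearest is not None:
            if self.nearest[0] not in probes:
                probes.append(self.nearest[0])
        if mode == "cometh+nn+seq" and self.sequence_match is not None:
            if self.sequence_match[0] not in probes:
                probes.append(self.sequence_match[0])
        return probes


def _distance_or_inf(
    manifest: ProbeManifest | None, model_probe: str, candidate: str
) -> float:
    if manifest is None or model_probe not in manifest or candidate not in manifest:
        return np.inf
    chrom_m, pos_m = manifest.position(model_probe)
    chrom_c, pos_c = manifest.position(candidate)
    if chrom_m != chrom_c:
        return np.inf
    return abs(pos_m - pos_c)


def _argmax_with_ties(
    candidates: list[str],
    scores: np.ndarray,
    model_probe: str,
    manifest: ProbeManifest | None,
) -> tuple[str, float] | None:
    finite = ~np.isnan(scores)
    if not finite.any():
        return None
    best = np.nanmax(scores)
    tied = [c for c, s in zip(candidates, scores) if not np.isnan(s) and s == best]
    if len(tied) > 1:
        tied.sort(key=lambda c: (_distance_or_inf(manifest, model_probe, c), c))
    return tied[0], float(best)


def select_comethylated(
    model_probe: str,
    training: MethylationMatrix,
    feature_loci: set[str] | list[str],
    manifest: ProbeManifest | None = None,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> tuple[str, float, int] | None:
    """Feature locus maximizing cross-sample Pearson correlation.

    Candidates with fewer than ``min_samples`` pairwise-complete
    training samples, zero variance on the overlap, or equal to the
    model probe itself are ineligible.  Returns
    ``(probe_id, r, n_used)`` or None when no candidate is eligible.
    """
    candidates = [p for p in training.probe_ids if p in set(feature_loci) and p != model_probe]
    if not candidates:
        return None
    y = training.values_for(model_probe)
    F = training.data.loc[candidates].to_numpy(dtype=float)
    r, n = _pearson_masked(y, F, min_samples=min_samples)
    pick = _argmax_with_ties(candidates, r, model_probe, manifest)
    if pick is None:
        return None
    probe, score = pick
    return probe, score, int(n[candidates.index(probe)])


def select_sequence_match(
    model_probe: str,
    seq_features: pd.DataFrame,
    feature_loci: set[str] | list[str],
    manifest: ProbeManifest | None = None,
) -> tuple[str, float] | None:
    """Feature locus with the most similar flanking-sequence composition.

    ``seq_features`` is a probe-indexed DataFrame of 340 k-mer
    frequencies.  Returns ``(probe_id, r)`` or None.
    """
    candidates = [
        p for p in seq_features.index if p in set(feature_loci) and p != model_probe
    ]
    if not candidates or model_probe not in seq_features.index:
        return None
    y = seq_features.loc[model_probe].to_numpy(dtype=float)
    F = seq_features.loc[candidates].to_numpy(dtype=float)
    r, _ = _pearson_masked(y, F, min_samples=2)
    return _argmax_with_ties(candidates, r, model_probe, manifest)


def nearest_neighbour(
    model_probe: str,
    manifest: ProbeManifest,
    feature_loci: set[str] | list[str],
    max_distance: int | None = None,
) -> tuple[str, int] | None:
    """Closest feature locus on the same chromosome, or None.

    With ``max_distance`` set (e.g. 2000 bp) candidates farther away are
    excluded, so a model locus may have no neighbour.  Ties (equal
    distance up- and downstream) break by probe ID.
    """
    if model_probe not in manifest:
        raise KeyError(f"model probe {model_probe!r} not in manifest")
    chrom, pos = manifest.position(model_probe)
    t = manifest.table
    cand = t.loc[t.index.isin(set(feature_loci)) & (t["chr"] == chrom)]
    cand = cand.drop(index=model_probe, errors="ignore")
    if cand.empty:
        return None
    dist = (cand["pos"] - pos).abs()
    if max_distance is not None:
        dist = dist[dist <= max_distance]
        if dist.empty:
            return None
    best = int(dist.min())
    tied = sorted(dist.index[dist == best])
    return tied[0], best


def sequence_feature_table(
    manifest: ProbeManifest,
    seqs: GenomeSequences,
    probes: list[str] | set[str],
    flank: int = 200,
) -> pd.DataFrame:
    """k-mer feature vectors of the flanking windows of ``probes``."""
    probes = sorted(probes)
    rows = np.empty((len(probes), N_KMER_FEATURES))
    for i, p in enumerate(probes):
        chrom, pos = manifest.position(p)
        rows[i] = kmer_features(fetch_flank(seqs, chrom, pos, flank=flank))
    return pd.DataFrame(rows, index=pd.Index(probes, name="probe_id"), columns=list(KMER_ORDER))


def build_assignments(
    manifest: ProbeManifest,
    training: MethylationMatrix,
    model_loci: set[str] | list[str],
    feature_loci: set[str] | list[str],
    seqs: GenomeSequences | None = None,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    nn_max_distance: int | None = None,
    flank: int = 200,
) -> tuple[dict[str, FeatureAssignment], list[str]]:
    """Select candidate features for every model locus from training samples only.

    Returns ``(assignments, excluded)`` where ``excluded`` lists model
    loci with no eligible co-methylated partner (e.g. constant across
    training samples or too few complete pairs).  Sequence-match
    features are computed only when ``seqs`` is given.
    """
    model_loci = sorted(set(model_loci))
    feature_set = set(feature_loci)
    seq_table = None
    if seqs is not None:
        seq_table = sequence_feature_table(
            manifest, seqs, set(model_loci) | feature_set, flank=flank
        )
    assignments: dict[str, FeatureAssignment] = {}
    excluded: list[str] = []
    for mp in model_loci:
        if mp not in training.data.index:
            excluded.append(mp)
            continue
        cometh = select_comethylated(
            mp, training, feature_set, manifest=manifest, min_samples=min_samples
        )
        if cometh is None:
            excluded.append(mp)
            continue
        probe, r, n_used = cometh
        fa = FeatureAssignment(
            model_probe_id=mp, comethylated=(probe, r), n_overlapping_samples=n_used
        )
        if mp in manifest:
            fa.nearest = nearest_neighbour(
                mp, manifest, feature_set, max_distance=nn_max_distance
            )
        if seq_table is not None:
            fa.sequence_match = select_sequence_match(
                mp, seq_table, feature_set, manifest=manifest
            )
        assignments[mp] = fa
    return assignments, excluded


def assignments_to_frame(assignments: dict[str, FeatureAssignment]) -> pd.DataFrame:
    """Tabular form: one row per model locus with all candidate features."""
    rows = []
    for mp in sorted(assignments):
        fa = assignments[mp]
        rows.append(
            {
                "model_probe": mp,
                "cometh_probe": fa.comethylated[0] if fa.comethylated else None,
                "cometh_r": fa.comethylated[1] if fa.comethylated else np.nan,
                "n_samples": fa.n_overlapping_samples,
                "nn_probe": fa.nearest[0] if fa.nearest else None,
                "nn_distance": fa.nearest[1] if fa.nearest else np.nan,
                "seq_probe": fa.sequence_match[0] if fa.sequence_match else None,
                "seq_r": fa.sequence_match[1] if fa.sequence_match else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "model_probe", "cometh_probe", "cometh_r", "n_samples",
            "nn_probe", "nn_distance", "seq_probe", "seq_r",
        ],
    )


def write_assignments(assignments: dict[str, FeatureAssignment], path) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False, na_rep="NA")
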