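"""Self-contained synthetic fixtures for every pipeline stage.

The generator emulates the statistical structure the per-locus models
assume: feature-locus betas with the bimodal marginal typical of array
data, model-locus betas tied to one planted partner through a sigmoid
link plus beta-scale Gaussian noise (clipped to [0, 1]), per-locus
noise tiers matching the accuracy categories, uniform missingness,
flanking sequences with controllable k-mer similarity between planted
pairs, and two-group matrices with planted mean-beta shifts for
differential-methylation power studies.

All randomness flows from ``SimulationSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrays_io import GenomeSequences, MethylationMatrix, ProbeManifest
from .locus_models import categorize, sigmoid

#: per-locus noise sd levels; one per accuracy tier the models distinguish
DEFAULT_NOISE_TIERS = (0.02, 0.07, 0.12, 0.2)

#: bimodal-plus-intermediate marginal of feature-locus betas
_MIXTURE = ((0.4, (0.5, 8.0)), (0.4, (8.0, 0.5)), (0.2, (2.0, 2.0)))


@dataclass
class SimulationSpec:
    """Parameters of one synthetic study.

    ``planted_links`` maps model-locus index → (feature-locus index, w, b);
    when None, links are assigned round-robin with slopes w ~ U(1.5, 2.5)
    and intercept b = −w/2, which keeps the noiseless response inside
    roughly [0.18, 0.82] so additive beta-scale noise is not materially
    censored by clipping.  ``noise_tiers`` are cycled across model loci.
    For grouped fixtures the samples split into two groups
    (n_samples // 2 and the remainder) and the first ``n_effect_loci``
    probes get a mean shift of ``group_delta`` (alternating sign,
    starting with group1 lower).
    """

    n_model_loci: int = 20
    n_feature_loci: int = 40
    n_samples: int = 100
    noise_tiers: tuple[float, ...] = DEFAULT_NOISE_TIERS
    missing_rate: float = 0.0
    planted_links: dict[int, tuple[int, float, float]] | None = None
    w_range: tuple[float, float] = (1.5, 2.5)
    seq_mutation_rate: float = 0.05
    flank: int = 200
    n_effect_loci: int = 0
    group_delta: float = 0.0
    group_noise_sd: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.noise_tiers):
            raise ValueError("noise sd must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.planted_links is not None:
            for mi, (fi, _, _) in self.planted_links.items():
                if not (0 <= fi < self.n_feature_loci):
                    raise ValueError(
                        f"planted link for model locus {mi} references "
                        f"feature index {fi} outside [0, {self.n_feature_loci})"
                    )
                if not (0 <= mi < self.n_model_loci):
                    raise ValueError(f"planted link references model index {mi}")
        if self.n_effect_loci > self.n_model_loci:
            raise ValueError("more effect loci than model loci")

    def model_probe(self, i: int) -> str:
        return f"cgM{i:05d}"

    def feature_probe(self, i: int) -> str:
        return f"cgF{i:05d}"


def _resolve_links(spec: SimulationSpec, rng: np.random.Generator):
    """(feature index, w, b, noise sd) per model locus."""
    links = []
    for i in range(spec.n_model_loci):
        if spec.planted_links is not None and i in spec.planted_links:
            fi, w, b = spec.planted_links[i]
        else:
            fi = i % spec.n_feature_loci
            w = rng.uniform(*spec.w_range)
            b = -w / 2.0
        sd = spec.noise_tiers[i % len(spec.noise_tiers)]
        links.append((fi, float(w), float(b), float(sd)))
    return links


def _feature_betas(rng: np.random.Generator, n_loci: int, n_samples: int) -> np.ndarray:
    """Per-cell draws from the bimodal-plus-intermediate beta mixture."""
    shape = (n_loci, n_samples)
    comp = rng.choice(len(_MIXTURE), size=shape, p=[w for w, _ in _MIXTURE])
    out = np.empty(shape)
    for ci, (_, (a, b)) in enumerate(_MIXTURE):
        mask = comp == ci
        out[mask] = rng.beta(a, b, size=int(mask.sum()))
    return out


def _random_chromosome(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length).tobytes())


def _mutate(core: bytes, rate: float, rng: np.random.Generator) -> bytes:
    out = bytearray(core)
    bases = b"ACGT"
    hits = np.where(rng.random(len(out)) < rate)[0]
    for i in hits:
        out[i] = bases[rng.integers(0, 4)]
    return bytes(out)


def _layout_manifest(spec: SimulationSpec, links) -> pd.DataFrame:
    """Coordinates exercising the distance regimes of neighbour search.

    Feature loci sit on chr1 every 10 kb.  Model locus i is placed, in
    rotation: within 2 kb of its partner (same chromosome), > 2 kb away
    on chr1, or on chr2 (no same-chromosome partner proximity).
    """
    genes = ["GENE_A;TSS200|GENE_B;Body", "GENE_B;Body", "GENE_C;TSS1500", ""]
    cgis = ["island", "shore", "shelf", "open sea"]
    rows = []
    for i in range(spec.n_feature_loci):
        rows.append(
            {
                "probe_id": spec.feature_probe(i),
                "chr": "chr1",
                "pos": 100_000 + 10_000 * i,
                "on450k": True,
                "onEPIC": True,
                "gene": genes[i % 4],
                "cgi": cgis[i % 4],
            }
        )
    feat_pos = {spec.feature_probe(i): 100_000 + 10_000 * i for i in range(spec.n_feature_loci)}
    base_far = 100_000 + 10_000 * spec.n_feature_loci + 1_000_000
    for i, (fi, _, _, _) in enumerate(links):
        kind = i % 3
        if kind == 0:  # adjacent to partner, < 2 kb
            chrom = "chr1"
            # unique, < 2 kb, and beyond the flanking window so planted
            # sequence cores never overwrite the partner's own window
            pos = feat_pos[spec.feature_probe(fi)] + 2 * spec.flank + 50 + i
        elif kind == 1:  # same chromosome, distal
            chrom = "chr1"
            pos = base_far + 5_000 * i
        else:  # different chromosome
            chrom = "chr2"
            pos = 50_000 + 5_000 * i
        rows.append(
            {
                "probe_id": spec.model_probe(i),
                "chr": chrom,
                "pos": pos,
                "on450k": False,
                "onEPIC": True,
                "gene": genes[(i + 1) % 4],
                "cgi": cgis[(i + 2) % 4],
            }
        )
    df = pd.DataFrame(rows)
    from .arrays_io import _parse_gene_annotation

    table = pd.DataFrame(
        {
            "chr": df["chr"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "on450k": df["on450k"].to_numpy(),
            "onEPIC": df["onEPIC"].to_numpy(),
            "gene_annotation": [_parse_gene_annotation(g) for g in df["gene"]],
            "cgi_relation": df["cgi"].to_numpy(),
        },
        index=pd.Index(df["probe_id"], name="probe_id"),
    )
    return table


def _build_sequences(
    spec: SimulationSpec, manifest: pd.DataFrame, links, rng: np.random.Generator
) -> GenomeSequences:
    """Random chromosomes; each model locus' flank is a mutated copy of its partner's."""
    window = 2 * spec.flank + 2
    chroms: dict[str, bytearray] = {}
    for chrom in sorted(manifest["chr"].unique()):
        length = int(manifest.loc[manifest["chr"] == chrom, "pos"].max()) + window + spec.flank
        chroms[chrom] = _random_chromosome(rng, length)

    def window_bounds(probe: str) -> tuple[str, int, int]:
        chrom = manifest.loc[probe, "chr"]
        pos = int(manifest.loc[probe, "pos"])
        start = max(1, pos - spec.flank)
        end = pos + spec.flank + 1
        return chrom, start, end

    for i, (fi, _, _, _) in enumerate(links):
        fchrom, fs, fe = window_bounds(spec.feature_probe(fi))
        core = bytes(chroms[fchrom][fs - 1 : fe])
        mchrom, ms, me = window_bounds(spec.model_probe(i))
        mutated = _mutate(core, spec.seq_mutation_rate, rng)[: me - ms + 1]
        chroms[mchrom][ms - 1 : ms - 1 + len(mutated)] = mutated
    return GenomeSequences({c: s.decode() for c, s in chroms.items()})


def generate_fixture(
    spec: SimulationSpec,
) -> tuple[MethylationMatrix, ProbeManifest, GenomeSequences, pd.DataFrame]:
    """Beta matrix + manifest + sequences + truth table for one planted study.

    The truth table has one row per model locus: the planted partner,
    link parameters (w, b), noise sd and the accuracy tier that sd
    implies (the category an exact model would earn in the absence of
    clipping and estimation error).
    """
    rng = np.random.default_rng(spec.seed)
    links = _resolve_links(spec, rng)
    feat = _feature_betas(rng, spec.n_feature_loci, spec.n_samples)
    model = np.empty((spec.n_model_loci, spec.n_samples))
    truth_rows = []
    for i, (fi, w, b, sd) in enumerate(links):
        clean = sigmoid(w * feat[fi] + b)
        noisy = clean + rng.normal(0.0, sd, size=spec.n_samples) if sd > 0 else clean
        model[i] = np.clip(noisy, 0.0, 1.0)
        truth_rows.append(
            {
                "model_probe": spec.model_probe(i),
                "partner_probe": spec.feature_probe(fi),
                "w": w,
                "b": b,
                "noise_sd": sd,
                "tier_category": categorize(sd),
            }
        )
    values = np.vstack([feat, model])
    probe_ids = [spec.feature_probe(i) for i in range(spec.n_feature_loci)] + [
        spec.model_probe(i) for i in range(spec.n_model_loci)
    ]
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)
    samples = [f"S{j:04d}" for j in range(spec.n_samples)]
    matrix = MethylationMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    )
    manifest_table = _layout_manifest(spec, links)
    seqs = _build_sequences(spec, manifest_table, links, rng)
    truth = pd.DataFrame(truth_rows)
    return matrix, ProbeManifest(manifest_table), seqs, truth


def generate_grouped_fixture(
    spec: SimulationSpec,
) -> tuple[MethylationMatrix, pd.Series, pd.DataFrame]:
    """Two-group beta matrix with planted mean shifts for DML power studies.

    Samples split into group1 (n_samples // 2, tumor semantics) and
    group2 (the rest).  The first ``n_effect_loci`` probes get a
    between-group mean difference of ``group_delta`` with alternating
    sign (even index: group1 lower, i.e. hypomethylated in group1).
    The truth table flags the planted DML set and its directions.
    """
    rng = np.random.default_rng(spec.seed)
    n1 = spec.n_samples // 2
    n2 = spec.n_samples - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("grouped fixture needs at least 2 samples")
    mu = rng.uniform(0.35, 0.65, size=spec.n_model_loci)
    probe_ids = [spec.model_probe(i) for i in range(spec.n_model_loci)]
    truth_rows = []
    values = np.empty((spec.n_model_loci, spec.n_samples))
    for i in range(spec.n_model_loci):
        is_effect = i < spec.n_effect_loci and spec.group_delta != 0
        sign = -1.0 if i % 2 == 0 else 1.0  # group1 − group2
        shift = sign * spec.group_delta / 2.0 if is_effect else 0.0
        g1 = mu[i] + shift + rng.normal(0.0, spec.group_noise_sd, size=n1)
        g2 = mu[i] - shift + rng.normal(0.0, spec.group_noise_sd, size=n2)
        values[i] = np.clip(np.concatenate([g1, g2]), 0.0, 1.0)
        truth_rows.append(
            {
                "probe_id": probe_ids[i],
                "is_dml": bool(is_effect),
                "delta_beta": 2 * shift,
                "direction": ("hypo" if sign < 0 else "hyper") if is_effect else "",
            }
        )
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)
    samples = [f"T{j:04d}" for j in range(n1)] + [f"N{j:04d}" for j in range(n2)]
    labels = pd.Series(
        ["group1"] * n1 + ["group2"] * n2, index=samples, name="group"
    )
    matrix = MethylationMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    )
    return matrix, labels, pd.DataFrame(truth_rows)
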