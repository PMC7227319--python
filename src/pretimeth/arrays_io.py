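"""Beta-matrix, manifest and sequence I/O plus array-level preprocessing.

Beta matrices are probes × samples tables of methylation fractions in
[0, 1] with missing entries allowed.  Manifests mirror the Illumina
450K/EPIC annotation columns this toolkit relies on: coordinates,
platform membership, gene/region annotation and CpG-island relation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}

CGI_RELATIONS = ("island", "shore", "shelf", "open sea")

#: Gene-region categories in 5'→3' priority order (highest first).
REGION_CATEGORIES = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")

# tokens seen in the wild for the same categories
_REGION_ALIASES = {
    "TSS200": "TSS200",
    "TSS1500": "TSS1500",
    "5'UTR": "5'UTR",
    "5UTR": "5'UTR",
    "1STEXON": "1stExon",
    "1ST EXON": "1stExon",
    "1EXON": "1stExon",
    "BODY": "Body",
    "3'UTR": "3'UTR",
    "3UTR": "3'UTR",
}

_CGI_ALIASES = {
    "ISLAND": "island",
    "N_SHORE": "shore",
    "S_SHORE": "shore",
    "SHORE": "shore",
    "N_SHELF": "shelf",
    "S_SHELF": "shelf",
    "SHELF": "shelf",
    "OPEN SEA": "open sea",
    "OPENSEA": "open sea",
    "OPEN_SEA": "open sea",
}


class BetaRangeError(ValueError):
    """A beta value lies outside [0, 1]."""


@dataclass
class MethylationMatrix:
    """Probes × samples beta values, NaN for missing.

    ``data`` is a float DataFrame indexed by probe ID with sample-ID
    columns; every non-missing value lies in [0, 1].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BetaRangeError(
                f"beta value {vals[i, j]!r} out of [0,1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values_for(self, probe_id: str) -> np.ndarray:
        """Cross-sample beta vector of one probe (NaN = missing)."""
        return self.data.loc[probe_id].to_numpy(dtype=float)


@dataclass
class ProbeManifest:
    """Per-probe coordinates and annotations.

    ``table`` is indexed by probe ID with columns ``chr`` (str),
    ``pos`` (1-based int), ``on450k``/``onEPIC`` (bool),
    ``gene_annotation`` (list of ``(gene, region)`` tuples) and
    ``cgi_relation`` (one of :data:`CGI_RELATIONS`).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe IDs in manifest: {dups[:5]}")
        if (self.table["pos"] < 1).any():
            raise ValueError("manifest positions must be >= 1 (1-based)")
        bad = set(self.table["cgi_relation"]) - set(CGI_RELATIONS)
        if bad:
            raise ValueError(f"invalid CGI relation tokens: {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.table.index

    def position(self, probe_id: str) -> tuple[str, int]:
        row = self.table.loc[probe_id]
        return str(row["chr"]), int(row["pos"])

    def gene_pairs(self, probe_id: str) -> list[tuple[str, str]]:
        return list(self.table.loc[probe_id, "gene_annotation"])


@dataclass
class GenomeSequences:
    """Per-chromosome nucleotide strings with 1-based inclusive lookup."""

    chromosomes: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequences":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, rebuild=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        """Sequence of ``[start, end]`` (1-based, inclusive), uppercased."""
        if chromosome not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        if start < 1 or end < start:
            raise ValueError(f"invalid 1-based range [{start}, {end}]")
        seq = self.chromosomes[chromosome]
        if end > len(seq):
            raise ValueError(
                f"range [{start}, {end}] exceeds {chromosome!r} length {len(seq)}"
            )
        return seq[start - 1 : end].upper()


def read_beta_matrix(path, sep: str | None = None) -> MethylationMatrix:
    """Read a delimited beta matrix (header = sample IDs, col 0 = probe ID).

    Empty, ``NA`` and ``NaN`` tokens become missing entries.  Values
    outside [0, 1] raise :class:`BetaRangeError` naming the offending
    probe and sample; ragged rows raise with the line number.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        sample_ids = header[1:]
        n_fields = len(header)
        probe_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(sep)
            if len(parts) != n_fields:
                raise ValueError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {n_fields}"
                )
            probe_ids.append(parts[0])
            rows.append(
                [np.nan if tok in MISSING_TOKENS else float(tok) for tok in parts[1:]]
            )
    data = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(probe_ids), len(sample_ids)),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=sample_ids,
    )
    return MethylationMatrix(data)


def write_beta_matrix(m: MethylationMatrix, path, sep: str | None = None) -> None:
    """Write a beta matrix; missing entries become ``NA``. Order preserved."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    out = m.data.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep=sep, na_rep="NA", float_format="%.10g")


def _parse_gene_annotation(token: str) -> list[tuple[str, str]]:
    token = token.strip()
    if not token:
        return []
    pairs = []
    for chunk in token.split("|"):
        gene, _, cat = chunk.partition(";")
        cat_norm = _REGION_ALIASES.get(cat.strip().upper().replace("_", ""))
        if cat_norm is None:
            cat_norm = _REGION_ALIASES.get(cat.strip().upper())
        if cat_norm is None:
            raise ValueError(f"unknown region category {cat!r} in {token!r}")
        pairs.append((gene.strip(), cat_norm))
    return pairs


def _parse_flag(tok) -> bool:
    return str(tok).strip().lower() in {"1", "true", "yes", "y"}


def read_manifest(path, sep: str = ",") -> ProbeManifest:
    """Read a probe manifest CSV.

    Required columns: probe_id, chr, pos, on450k, onEPIC,
    gene_annotation (``GENE;CATEGORY|GENE;CATEGORY``), cgi_relation.
    Unknown CGI tokens map to ``open sea`` with a warning (Illumina
    manifests leave the field blank for open-sea probes).
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"probe_id", "chr", "pos", "on450k", "onEPIC", "gene_annotation", "cgi_relation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing required columns: {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicate probe IDs in manifest: {dups[:5]}")

    def norm_cgi(tok: str) -> str:
        mapped = _CGI_ALIASES.get(tok.strip().upper())
        if mapped is None:
            if tok.strip():
                logger.warning("unknown CGI token %r mapped to 'open sea'", tok)
            return "open sea"
        return mapped

    table = pd.DataFrame(
        {
            "chr": df["chr"].str.strip().to_numpy(),
            "pos": df["pos"].astype(int).to_numpy(),
            "on450k": df["on450k"].map(_parse_flag).to_numpy(),
            "onEPIC": df["onEPIC"].map(_parse_flag).to_numpy(),
            "gene_annotation": pd.Series(
                [_parse_gene_annotation(g) for g in df["gene_annotation"]], dtype=object
            ).to_numpy(),
            "cgi_relation": df["cgi_relation"].map(norm_cgi).to_numpy(),
        },
        index=pd.Index(df["probe_id"].str.strip().to_numpy(), name="probe_id"),
    )
    return ProbeManifest(table)


def write_manifest(manifest: ProbeManifest, path, sep: str = ",") -> None:
    t = manifest.table
    out = pd.DataFrame(
        {
            "probe_id": t.index,
            "chr": t["chr"].to_numpy(),
            "pos": t["pos"].to_numpy(),
            "on450k": t["on450k"].astype(int).to_numpy(),
            "onEPIC": t["onEPIC"].astype(int).to_numpy(),
            "gene_annotation": [
                "|".join(f"{g};{c}" for g, c in pairs) for pairs in t["gene_annotation"]
            ],
            "cgi_relation": t["cgi_relation"].to_numpy(),
        }
    )
    out.to_csv(path, sep=sep, index=False)


def partition_loci(manifest: ProbeManifest) -> tuple[set[str], set[str]]:
    """Split probes into model loci (EPIC-only) and feature loci (both chips).

    Model loci are covered by the EPIC array but not the 450K array and
    are the targets of per-locus prediction; feature loci sit on both
    platforms and are the candidate predictors.  Probes on neither
    platform are excluded (counted in a warning).
    """
    t = manifest.table
    model = set(t.index[t["onEPIC"] & ~t["on450k"]])
    feature = set(t.index[t["onEPIC"] & t["on450k"]])
    n_orphan = int((~t["onEPIC"]).sum() - (t["on450k"] & ~t["onEPIC"]).sum())
    if n_orphan > 0:
        logger.warning("%d probes flagged on neither platform were excluded", n_orphan)
    return model, feature


def quantile_normalize(m: MethylationMatrix) -> MethylationMatrix:
    """Quantile-normalize samples against the across-sample mean quantile curve.

    The reference curve is the mean of the sorted per-sample values over
    probes with complete data.  Samples with missing entries are ranked
    on their non-missing values and mapped onto the reference curve by
    linear interpolation of quantile positions; tied values receive the
    mean of the reference quantiles at their tied ranks.

    For complete data this is ordinary quantile normalization: every
    output column's multiset of values equals the reference curve and
    within-sample ranks are preserved.
    """
    data = m.data.to_numpy(dtype=float)
    n_probes, n_samples = data.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    nonmiss = ~np.isnan(data)
    if (nonmiss.sum(axis=0) == 0).any():
        empty = [m.sample_ids[j] for j in np.where(nonmiss.sum(axis=0) == 0)[0]]
        raise ValueError(f"samples with zero non-missing values: {empty}")
    complete_rows = nonmiss.all(axis=1)
    if not complete_rows.any():
        raise ValueError("no complete probe rows to build the reference quantile curve")
    ref = np.sort(data[complete_rows], axis=0).mean(axis=1)
    L = ref.size

    out = np.full_like(data, np.nan)
    for j in range(n_samples):
        x = data[nonmiss[:, j], j]
        n = x.size
        if n == 1:
            mapped = np.array([ref.mean()])
        else:
            # reference quantiles at this sample's n rank positions
            qpos = np.linspace(0.0, 1.0, n)
            refpos = np.linspace(0.0, 1.0, L)
            curve = np.interp(qpos, refpos, ref)
            order = np.argsort(x, kind="stable")
            mapped = np.empty(n)
            mapped[order] = curve
            # average-rank convention for ties
            if np.unique(x).size < n:
                mapped = (
                    pd.Series(mapped).groupby(pd.Series(x)).transform("mean").to_numpy()
                )
        out[nonmiss[:, j], j] = mapped
    return MethylationMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    )


def fetch_flank(
    seqs: GenomeSequences, chromosome: str, position: int, flank: int = 200
) -> str:
    """Flanking window around a CpG, uppercased.

    The CpG dinucleotide occupies ``[position, position+1]``; the window
    is ``[position-flank, position+flank+1]`` (1-based inclusive),
    clipped at chromosome ends without padding.
    """
    if chromosome not in seqs.chromosomes:
        raise KeyError(f"unknown chromosome {chromosome!r}")
    chrom_len = len(seqs.chromosomes[chromosome])
    start = max(1, position - flank)
    end = min(chrom_len, position + flank + 1)
    if start > chrom_len or end < 1:
        return ""
    return seqs.fetch(chromosome, start, end)
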