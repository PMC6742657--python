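"""Reading, validation, filtering and normalization of peptide-ion tables.

The expected table layout is the one produced by MS alignment software
exports: one row per peptide ion with its sequence, modification string,
parent protein accession, uniqueness flag, identification score, and one raw
intensity column per sample. Missing intensities are empty cells and stay
missing (ion non-detection is censoring, not a measured zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .stats import bh_adjust

logger = logging.getLogger(__name__)

FIXED_COLUMNS = ["peptide_id", "sequence", "modifications", "accession", "unique", "score"]


@dataclass(frozen=True)
class ModEntry:
    label: str
    mass_delta: float  # Daltons, monoisotopic
    residues: str  # one-letter codes the modification may sit on


@dataclass
class MassDeltaRegistry:
    entries: list[ModEntry]

    def __post_init__(self):
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("modification labels must be unique")
        if any(e.mass_delta <= 0 for e in self.entries):
            raise ValueError("mass deltas must be positive")
        self._by_label = {e.label: e for e in self.entries}

    def get(self, label: str) -> ModEntry:
        return self._by_label[label]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label


def default_registry() -> MassDeltaRegistry:
    """Modifications searched in the source experiments (monoisotopic Da)."""
    return MassDeltaRegistry(
        [
            ModEntry("carbamidomethyl", 57.021, "C"),
            ModEntry("oxidation", 15.995, "M"),
            ModEntry("hydroxylation", 15.995, "NDPK"),
            ModEntry("phospho", 79.966, "SYTHD"),
            ModEntry("mBBr", 133.053, "C"),
            ModEntry("mBBr-ox", 150.056, "C"),
        ]
    )


@dataclass(frozen=True)
class SiteAnnotation:
    """A PTM localized onto the protein sequence."""

    protein_accession: str
    residue: str
    protein_position: int  # 1-based
    label: str
    ambiguous: bool
    peptide_id: str

    @property
    def site(self) -> str:
        return f"{self.residue}{self.protein_position}"


@dataclass
class ExperimentDesign:
    """Sample -> (treatment group, donor) mapping with a reference group."""

    samples: pd.DataFrame  # columns: sample_id, group, donor
    reference_group: str

    def __post_init__(self):
        required = {"sample_id", "group", "donor"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("sample_ids must be unique")
        groups = self.groups
        if len(groups) < 2:
            raise ValueError("design must contain at least 2 groups")
        if self.reference_group not in groups:
            raise ValueError(f"reference group {self.reference_group!r} not among groups {groups}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def groups(self) -> list[str]:
        seen = list(dict.fromkeys(self.samples["group"]))
        return seen

    @property
    def donors(self) -> list[str]:
        return list(dict.fromkeys(self.samples["donor"]))

    def group_of(self, sample_id: str) -> str:
        row = self.samples.loc[self.samples["sample_id"] == sample_id]
        return row["group"].iloc[0]


def _parse_modifications(text, sequence: str, row_number: int) -> list[tuple[int, float, str]]:
    """Parse 'offset:label;offset:label' into (offset, mass_delta, label)."""
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return []
    mods = []
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        parts = token.split(":")
        if len(parts) != 2:
            raise ValueError(f"row {row_number}: malformed modification string {token!r}")
        try:
            offset = int(parts[0])
        except ValueError as exc:
            raise ValueError(f"row {row_number}: malformed modification offset {parts[0]!r}") from exc
        label = parts[1]
        if offset < 1 or offset > len(sequence):
            raise ValueError(
                f"row {row_number}: modification offset {offset} outside peptide "
                f"of length {len(sequence)}"
            )
        mods.append((offset, label))
    return mods


@dataclass
class PeptideTable:
    """Collection of peptide-ion observations (wide layout, one intensity
    column per sample). Intensities may be raw (positive) or log2-normalized
    after :func:`log_and_normalize`."""

    df: pd.DataFrame
    sample_ids: list[str]
    registry: MassDeltaRegistry = field(default_factory=default_registry)
    log_scale: bool = False

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "PeptideTable":
        return PeptideTable(self.df.copy(), list(self.sample_ids), self.registry, self.log_scale)

    def validate(self) -> None:
        df = self.df
        for col in FIXED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        if (df["score"] < 0).any():
            raise ValueError("id scores must be >= 0")
        intens = df[self.sample_ids].to_numpy(dtype=float)
        if not self.log_scale and np.nanmin(intens, initial=np.inf) <= 0:
            raise ValueError("raw intensities must be positive where present")
        for i, (seq, mods) in enumerate(zip(df["sequence"], df["modifications"])):
            _parse_modifications(mods, seq, i + 2)  # +2: header + 1-based rows

    def modifications_of(self, row) -> list[tuple[int, float, str]]:
        """(peptide_offset, mass_delta, label) triples for one row."""
        out = []
        for offset, label in _parse_modifications(row["modifications"], row["sequence"], -1):
            delta = self.registry.get(label).mass_delta if label in self.registry else float("nan")
            out.append((offset, delta, label))
        return out

    @property
    def accessions(self) -> list[str]:
        return list(dict.fromkeys(self.df["accession"]))


def read_peptide_table(
    path,
    design: ExperimentDesign | None = None,
    registry: MassDeltaRegistry | None = None,
) -> PeptideTable:
    """Read a peptide-ion CSV. Columns: peptide_id, sequence, modifications,
    accession, unique, score, then one column per sample. Empty intensity
    cells become missing (NaN), never zero."""
    registry = registry or default_registry()
    df = pd.read_csv(path, dtype={"peptide_id": str, "sequence": str, "accession": str})
    for col in FIXED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"peptide table {path} lacks required column {col!r}")
    sample_ids = [c for c in df.columns if c not in FIXED_COLUMNS]
    if design is not None:
        unknown = set(sample_ids) - set(design.sample_ids)
        if unknown:
            raise ValueError(f"unknown sample column(s) not in design: {sorted(unknown)}")
        missing = set(design.sample_ids) - set(sample_ids)
        if missing:
            raise ValueError(f"design sample(s) absent from table: {sorted(missing)}")
    df["modifications"] = df["modifications"].fillna("")
    df["unique"] = df["unique"].astype(bool)
    df[sample_ids] = df[sample_ids].astype(float)
    table = PeptideTable(df, sample_ids, registry)
    table.validate()
    for offset, label in [
        (o, l)
        for _, row in df.iterrows()
        for (o, l) in _parse_modifications(row["modifications"], row["sequence"], -1)
    ]:
        if label not in registry:
            raise ValueError(f"unknown modification label {label!r}")
    return table


def write_peptide_table(table: PeptideTable, path) -> None:
    """Write in the canonical CSV dialect read_peptide_table consumes."""
    cols = FIXED_COLUMNS + table.sample_ids
    out = table.df[cols].copy()
    out["unique"] = out["unique"].astype(bool)
    out.to_csv(path, index=False)


def read_design(path, reference_group: str) -> ExperimentDesign:
    df = pd.read_csv(path, dtype=str)
    return ExperimentDesign(df[["sample_id", "group", "donor"]], reference_group)


def write_design(design: ExperimentDesign, path) -> None:
    design.samples.to_csv(path, index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Pathway membership sets from a GMT file (name, description, members...)."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = set(p for p in parts[2:] if p)
    return pathways


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_fold_changes(path, key: str = "gene") -> pd.DataFrame:
    """Per-gene log fold-change TSV keyed by ``key``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if key not in df.columns:
        raise ValueError(f"fold-change table lacks join key column {key!r}")
    return df


def read_morphometry(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "donor": str, "group": str})
    required = {"cell_id", "donor", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"morphometry table needs columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------


def filter_by_confidence(table: PeptideTable, fdr_threshold: float = 0.2) -> PeptideTable:
    """Keep peptides whose identification passes a BH-FDR threshold.

    Scores are mapped to p-values by the Mascot identity p = 10^(-S/10),
    BH-adjusted across the whole table; peptides with q >= threshold are
    removed.
    """
    if len(table) == 0:
        raise ValueError("cannot confidence-filter an empty peptide table")
    if not (0 < fdr_threshold <= 1):
        raise ValueError("fdr_threshold must lie in (0, 1]")
    p = np.power(10.0, -table.df["score"].to_numpy(dtype=float) / 10.0)
    p = np.minimum(p, 1.0)
    q = bh_adjust(p)
    keep = q < fdr_threshold
    logger.info("confidence filter: kept %d/%d peptide ions", int(keep.sum()), len(table))
    out = table.copy()
    out.df = out.df.loc[keep].reset_index(drop=True)
    return out


def filter_by_peptide_count(table: PeptideTable, min_unique: int = 3) -> PeptideTable:
    """Drop proteins identified by fewer than ``min_unique`` distinct unique
    peptide sequences (all their rows are removed)."""
    df = table.df
    uniq = df.loc[df["unique"]]
    counts = uniq.groupby("accession")["sequence"].nunique()
    keep_acc = set(counts.index[counts >= min_unique])
    keep = df["accession"].isin(keep_acc)
    dropped = df.loc[~keep, "accession"].nunique()
    if dropped:
        logger.info("peptide-count filter: removed %d protein(s)", dropped)
    out = table.copy()
    out.df = df.loc[keep].reset_index(drop=True)
    return out


def log_and_normalize(table: PeptideTable) -> PeptideTable:
    """log2-transform intensities and subtract each sample's median so every
    sample's median transformed intensity is 0. Missing cells stay missing."""
    if table.log_scale:
        raise ValueError("table is already on the log scale")
    out = table.copy()
    for sid in table.sample_ids:
        col = out.df[sid].to_numpy(dtype=float)
        present = np.isfinite(col)
        if not present.any():
            raise ValueError(f"sample {sid!r} has no present intensities")
        logged = np.where(present, np.log2(np.where(present, col, 1.0)), np.nan)
        logged[present] -= np.median(logged[present])
        out.df[sid] = logged
    out.log_scale = True
    return out


def annotate_ptm_sites(
    table: PeptideTable,
    proteome: dict[str, str],
    registry: MassDeltaRegistry | None = None,
) -> list[SiteAnnotation]:
    """Locate each modified peptide in its protein by leftmost exact substring
    match and emit per-site annotations; multiple matches set ambiguous."""
    registry = registry or table.registry
    annotations: list[SiteAnnotation] = []
    for _, row in table.df.iterrows():
        mods = _parse_modifications(row["modifications"], row["sequence"], -1)
        if not mods:
            continue
        acc = row["accession"]
        if acc not in proteome:
            raise ValueError(f"protein {acc!r} absent from proteome")
        protein = proteome[acc]
        pos = protein.find(row["sequence"])
        if pos < 0:
            raise ValueError(
                f"peptide {row['sequence']!r} is not a substring of protein {acc!r}"
            )
        ambiguous = protein.find(row["sequence"], pos + 1) >= 0
        for offset, label in mods:
            protein_position = pos + offset  # pos is 0-based; offset 1-based
            residue = protein[protein_position - 1]
            if label in registry and residue not in registry.get(label).residues:
                logger.warning(
                    "site %s%d on %s inconsistent with %s-allowed residues",
                    residue, protein_position, acc, label,
                )
            annotations.append(
                SiteAnnotation(
                    protein_accession=acc,
                    residue=residue,
                    protein_position=protein_position,
                    label=label,
                    ambiguous=ambiguous,
                    peptide_id=row["peptide_id"],
                )
            )
    return annotations
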