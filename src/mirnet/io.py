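"""Readers and validators for expression matrices, sample sheets, alias
tables, miRNA→target maps and GMT gene-set collections.

Expression values are assumed to be already log2-transformed and
normalised; nothing here rescales data. All gene symbols are upper-cased on
load so joins between target maps and gene sets are case-insensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("normal", "tumour")


class ValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


@dataclass
class ExpressionStudy:
    """A paired expression study.

    Parameters
    ----------
    values
        Feature × sample matrix of log2 intensities. Index = miRNA ids,
        columns = sample ids.
    samples
        Sample sheet indexed by sample id with columns ``subject_id``,
        ``tissue`` (``normal`` or ``tumour``) and ``cohort``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_pairs(self) -> int:
        return self.samples["subject_id"].nunique()

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.samples["cohort"].unique())

    def stratum(self, tissue: str | None = None,
                cohort: str | None = None) -> pd.DataFrame:
        """Sub-matrix restricted to one tissue and/or cohort."""
        mask = pd.Series(True, index=self.samples.index)
        if tissue is not None:
            if tissue not in TISSUES:
                raise ValidationError(f"unknown tissue {tissue!r}")
            mask &= self.samples["tissue"] == tissue
        if cohort is not None:
            mask &= self.samples["cohort"] == cohort
        return self.values.loc[:, self.samples.index[mask]]

    def subset_cohort(self, cohort: str) -> "ExpressionStudy":
        keep = self.samples.index[self.samples["cohort"] == cohort]
        return ExpressionStudy(self.values.loc[:, keep],
                               self.samples.loc[keep].copy())

    def paired_differences(self, cohort: str | None = None) -> pd.DataFrame:
        """Feature × subject matrix of within-subject log2 differences
        (tumour − normal), subjects in sorted order."""
        samples = self.samples
        if cohort is not None:
            samples = samples[samples["cohort"] == cohort]
        subjects = sorted(samples["subject_id"].unique())
        cols = {}
        for subj in subjects:
            rows = samples[samples["subject_id"] == subj]
            t = rows.index[rows["tissue"] == "tumour"]
            n = rows.index[rows["tissue"] == "normal"]
            if len(t) != 1 or len(n) != 1:
                raise ValidationError(
                    f"subject {subj!r} lacks a complete normal/tumour pair")
            cols[subj] = self.values[t[0]] - self.values[n[0]]
        return pd.DataFrame(cols, index=self.values.index)

    def validate(self) -> "ExpressionStudy":
        """Enforce invariants: unique ids, complete pairs, no missing values
        (features with any missing value are dropped with a warning)."""
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        missing = self.values.isna().any(axis=1)
        if missing.any():
            dropped = list(self.values.index[missing])
            logger.warning("dropping %d feature(s) with missing values: %s",
                           len(dropped), ", ".join(dropped[:5]))
            self.values = self.values.loc[~missing]
        bad = set(self.samples["tissue"]) - set(TISSUES)
        if bad:
            raise ValidationError(f"unknown tissue label(s) {sorted(bad)}")
        for (cohort, subj), rows in self.samples.groupby(
                ["cohort", "subject_id"]):
            tissues = sorted(rows["tissue"])
            if tissues != ["normal", "tumour"]:
                raise ValidationError(
                    f"subject {subj!r} (cohort {cohort!r}) has tissues "
                    f"{tissues}, expected one normal and one tumour sample")
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionStudy):
            return NotImplemented
        return (self.values.equals(other.values)
                and self.samples.equals(other.samples))


@dataclass
class AliasTable:
    """Legacy miRNA symbol → (current symbol, stable accession)."""

    mapping: dict[str, tuple[str, str]] = field(default_factory=dict)

    def current(self, legacy: str) -> str:
        return self.mapping.get(legacy, (legacy, ""))[0]

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class TargetMap:
    """miRNA id → set of validated target gene symbols (upper-cased)."""

    targets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.targets

    def __getitem__(self, mirna: str) -> frozenset[str]:
        return self.targets[mirna]

    def __len__(self) -> int:
        return len(self.targets)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested in.

    ``universe`` defaults to the union of all member genes when not given
    explicitly.
    """

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.universe:
            u: set[str] = set()
            for members in self.sets.values():
                u |= members
            self.universe = frozenset(u)
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            extra = members - self.universe
            if extra:
                raise ValidationError(
                    f"gene set {name!r} has members outside the declared "
                    f"universe: {sorted(extra)[:5]}")

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    def __len__(self) -> int:
        return len(self.sets)


def read_study(matrix_path: str | Path,
               samples_path: str | Path) -> ExpressionStudy:
    """Read an expression matrix and its sample sheet.

    The matrix is tab-delimited with the feature id in the first column and
    one column per sample; the sample sheet has columns ``sample_id``,
    ``subject_id``, ``tissue`` and ``cohort``. Only samples present in both
    files are kept, and study invariants (unique ids, complete pairs, no
    missing values) are enforced.
    """
    matrix_path, samples_path = Path(matrix_path), Path(samples_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    non_numeric = values.columns[
        [not np.issubdtype(dt, np.number) for dt in values.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()
                          & values[col].notna()]
        where = f"row {bad.index[0]!r}" if len(bad) else "unknown row"
        raise ValidationError(
            f"non-numeric value in column {col!r} ({where})")
    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    required = {"sample_id", "subject_id", "tissue", "cohort"}
    if not required.issubset(samples.columns):
        raise ValidationError(
            f"sample sheet missing column(s) {sorted(required - set(samples.columns))}")
    if samples["sample_id"].duplicated().any():
        dup = samples["sample_id"][samples["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample id {dup!r} in sample sheet")
    samples = samples.set_index("sample_id")
    shared = [s for s in values.columns if s in samples.index]
    if not shared:
        raise ValidationError("no sample ids shared between matrix and sheet")
    study = ExpressionStudy(values.loc[:, shared].astype(float),
                            samples.loc[shared])
    return study.validate()


def write_study(study: ExpressionStudy, matrix_path: str | Path,
                samples_path: str | Path) -> None:
    """Write a study back to the TSV formats read by :func:`read_study`."""
    study.values.to_csv(Path(matrix_path), sep="\t",
                        index_label="feature_id")
    study.samples.to_csv(Path(samples_path), sep="\t",
                         index_label="sample_id")


def apply_aliases(study: ExpressionStudy,
                  aliases: AliasTable) -> ExpressionStudy:
    """Rename features to their current symbols.

    When two legacy ids map to the same current symbol the feature with the
    higher mean intensity survives; the other is dropped with a warning.
    Unmapped ids pass through unchanged.
    """
    new_names = [aliases.current(f) for f in study.features]
    values = study.values.copy()
    values.index = pd.Index(new_names, name=values.index.name)
    if values.index.duplicated().any():
        means = values.mean(axis=1)
        keep_rows = []
        seen_best: dict[str, int] = {}
        for i, name in enumerate(values.index):
            if name not in seen_best:
                seen_best[name] = i
            elif means.iloc[i] > means.iloc[seen_best[name]]:
                seen_best[name] = i
        collided = [n for n, c in
                    values.index.value_counts().items() if c > 1]
        logger.warning("alias collision on %s; keeping the feature with "
                       "higher mean intensity", ", ".join(map(str, collided)))
        keep_rows = sorted(seen_best.values())
        values = values.iloc[keep_rows]
    return ExpressionStudy(values, study.samples.copy())


def read_alias_table(path: str | Path) -> AliasTable:
    """Read a 3-column TSV: legacy symbol, current symbol, accession."""
    mapping: dict[str, tuple[str, str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{path}: malformed alias line {lineno}")
        legacy, current = parts[0], parts[1]
        accession = parts[2] if len(parts) > 2 else ""
        if legacy in mapping and mapping[legacy][0] != current:
            raise ValidationError(
                f"{path}: line {lineno}: legacy id {legacy!r} maps to more "
                f"than one current symbol")
        mapping[legacy] = (current, accession)
    return AliasTable(mapping)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (tab-delimited: name, description, member genes)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{path}: line {lineno}: GMT line needs name, description "
                f"and at least one gene")
        name, desc = parts[0], parts[1]
        genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
        if not genes:
            raise ValidationError(f"{path}: line {lineno}: empty gene set")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def read_target_map(path: str | Path) -> TargetMap:
    """Read a two-column TSV of (mirna_id, gene_symbol) pairs."""
    targets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            raise ValidationError(
                f"{path}: line {lineno}: expected 'mirna<TAB>gene'")
        targets.setdefault(parts[0].strip(), set()).add(
            parts[1].strip().upper())
    return TargetMap({m: frozenset(g) for m, g in targets.items()})
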