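"""Domain types and I/O for case-control SNP panel studies.

The central container is :class:`GenotypeStudy`: a subjects x SNPs matrix of
minor-allele counts (0/1/2) together with the phenotype (``case`` = long-lived,
``control`` = middle-aged), sex, and — for cases — censored follow-up survival.
Genotype files are accepted either as a plain TSV dialect or as PLINK
``.raw``-style additive recodings.

Missing genotypes are stored as the sentinel :data:`MISSING` (never 0, which
would silently inflate reference homozygotes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Internal sentinel for a missing genotype call.
MISSING: int = -1

#: Tokens accepted as "missing" in genotype files.
MISSING_TOKENS = frozenset({"NA", "", "-9", ".", "nan", "NaN"})

#: Default pathway label set (insulin/IGF-1 signalling, DNA damage signalling
#: and repair, pro/antioxidant response).
DEFAULT_PATHWAYS: tuple[str, ...] = ("IIS", "DNA_repair", "pro_antioxidant")

PHENOTYPE_LABELS = ("case", "control")
SEX_LABELS = ("male", "female", "unknown")

# Condition sets for GenotypeCombination loci, in minor-allele-count coding.
EXACT = {0: frozenset({0}), 1: frozenset({1}), 2: frozenset({2})}
CARRIER_MINOR = frozenset({1, 2})  # >= 1 copy of the minor allele
CARRIER_MAJOR = frozenset({0, 1})  # >= 1 copy of the major allele
ANY_GENOTYPE = frozenset({0, 1, 2})


class DataValidationError(ValueError):
    """Raised when an input file or container violates a structural invariant."""


@dataclass
class GenotypeStudy:
    """Subjects x SNPs study with phenotype, sex and optional survival columns.

    Parameters
    ----------
    subject_ids
        Unique subject identifiers, one per row of ``genotypes``.
    phenotype
        Per-subject label, ``"case"`` or ``"control"``.
    sex
        Per-subject label in ``{"male", "female", "unknown"}``.
    genotypes
        ``(n_subjects, n_snps)`` integer matrix of minor-allele counts with
        :data:`MISSING` for no-calls.
    snp_ids
        Column identifiers, same order as the matrix columns.
    survival_months
        Optional per-subject non-negative follow-up in months (NaN where not
        applicable, i.e. controls). Present iff ``event`` is present.
    event
        Optional per-subject death indicator (1 = death observed,
        0 = censored, NaN where not applicable).
    """

    subject_ids: list[str]
    phenotype: np.ndarray
    sex: np.ndarray
    genotypes: np.ndarray
    snp_ids: list[str]
    survival_months: np.ndarray | None = None
    event: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.phenotype = np.asarray(self.phenotype, dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.survival_months is not None:
            self.survival_months = np.asarray(self.survival_months, dtype=float)
        if self.event is not None:
            self.event = np.asarray(self.event, dtype=float)
        self.validate()

    # ------------------------------------------------------------------ checks
    def validate(self) -> None:
        n, m = self.genotypes.shape
        if len(self.subject_ids) != n:
            raise DataValidationError(
                f"{len(self.subject_ids)} subject ids for {n} genotype rows"
            )
        if len(self.snp_ids) != m:
            raise DataValidationError(f"{len(self.snp_ids)} snp ids for {m} columns")
        seen: set[str] = set()
        for sid in self.subject_ids:
            if sid in seen:
                raise DataValidationError(f"duplicate subject id: {sid!r}")
            seen.add(sid)
        if len(set(self.snp_ids)) != m:
            raise DataValidationError("duplicate SNP ids in header")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DataValidationError(
                f"genotype value {int(self.genotypes[r, c])} outside {{0,1,2,missing}} "
                f"at subject {self.subject_ids[r]!r}, SNP {self.snp_ids[c]!r}"
            )
        for lab in np.unique(self.phenotype):
            if lab not in PHENOTYPE_LABELS:
                raise DataValidationError(f"unknown phenotype label {lab!r}")
        for lab in np.unique(self.sex):
            if lab not in SEX_LABELS:
                raise DataValidationError(f"unknown sex label {lab!r}")
        if (self.survival_months is None) != (self.event is None):
            raise DataValidationError("survival_months present iff event present")
        if self.survival_months is not None:
            with np.errstate(invalid="ignore"):
                if np.any(self.survival_months < 0):
                    raise DataValidationError("negative survival_months")
            if not np.array_equal(
                np.isnan(self.survival_months), np.isnan(self.event)
            ):
                raise DataValidationError("survival/event missingness mismatch")

    # -------------------------------------------------------------- accessors
    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype == "case"

    def require_both_groups(self) -> None:
        n_case = int(self.case_mask.sum())
        if n_case == 0 or n_case == self.n_subjects:
            raise DataValidationError(
                "association analysis needs at least one case and one control"
            )

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self.snp_index(snp_id)]

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeStudy":
        """New study restricted to ``snp_ids`` (given order); subjects unchanged."""
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeStudy(
            subject_ids=list(self.subject_ids),
            phenotype=self.phenotype.copy(),
            sex=self.sex.copy(),
            genotypes=self.genotypes[:, idx].copy(),
            snp_ids=[self.snp_ids[i] for i in idx],
            survival_months=None
            if self.survival_months is None
            else self.survival_months.copy(),
            event=None if self.event is None else self.event.copy(),
        )

    def subset_subjects(self, mask: np.ndarray) -> "GenotypeStudy":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeStudy(
            subject_ids=[s for s, k in zip(self.subject_ids, mask) if k],
            phenotype=self.phenotype[mask],
            sex=self.sex[mask],
            genotypes=self.genotypes[mask],
            snp_ids=list(self.snp_ids),
            survival_months=None
            if self.survival_months is None
            else self.survival_months[mask],
            event=None if self.event is None else self.event[mask],
        )


# ---------------------------------------------------------------- annotation


@dataclass(frozen=True)
class SnpAnnotation:
    """One SNP's gene, pathway and map position (1-based)."""

    snp_id: str
    gene: str
    pathway: str
    chromosome: str
    position: int


class SnpAnnotationTable:
    """Validated collection of :class:`SnpAnnotation` rows with fast lookups."""

    def __init__(
        self,
        records: Iterable[SnpAnnotation],
        pathways: Sequence[str] = DEFAULT_PATHWAYS,
    ) -> None:
        self.pathways = tuple(pathways)
        self.records: list[SnpAnnotation] = []
        self._by_id: dict[str, SnpAnnotation] = {}
        for rec in records:
            if rec.pathway not in self.pathways:
                raise DataValidationError(
                    f"unknown pathway {rec.pathway!r} for SNP {rec.snp_id!r}; "
                    f"allowed: {sorted(self.pathways)}"
                )
            if rec.position < 0:
                raise DataValidationError(f"negative position for {rec.snp_id!r}")
            if rec.snp_id in self._by_id:
                raise DataValidationError(f"duplicate annotation for {rec.snp_id!r}")
            self.records.append(rec)
            self._by_id[rec.snp_id] = rec
        if not self.records:
            logger.warning("annotation table is empty")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._by_id

    def get(self, snp_id: str) -> SnpAnnotation | None:
        return self._by_id.get(snp_id)

    def gene(self, snp_id: str) -> str:
        rec = self._by_id.get(snp_id)
        return rec.gene if rec else ""

    def pathway(self, snp_id: str) -> str:
        rec = self._by_id.get(snp_id)
        return rec.pathway if rec else ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.snp_id, r.gene, r.pathway, r.chromosome, r.position)
                for r in self.records
            ],
            columns=["snp_id", "gene", "pathway", "chromosome", "position"],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_annotation(
    path, pathways: Sequence[str] = DEFAULT_PATHWAYS
) -> SnpAnnotationTable:
    """Read a SNP annotation TSV (snp_id, gene, pathway, chromosome, position)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "gene", "pathway", "chromosome", "position"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise DataValidationError(f"annotation missing columns: {missing_cols}")
    records = [
        SnpAnnotation(
            snp_id=row.snp_id,
            gene=row.gene,
            pathway=row.pathway,
            chromosome=str(row.chromosome),
            position=int(row.position),
        )
        for row in df.itertuples()
    ]
    return SnpAnnotationTable(records, pathways=pathways)


def subset_by_pathway(
    study: GenotypeStudy,
    ann: SnpAnnotationTable,
    pathways: Iterable[str],
) -> GenotypeStudy:
    """Restrict a study to the SNPs annotated to the requested pathways."""
    requested = set(pathways)
    unknown = requested - set(ann.pathways)
    if unknown:
        raise DataValidationError(
            f"pathways {sorted(unknown)} not in declared set {sorted(ann.pathways)}"
        )
    keep = [s for s in study.snp_ids if ann.pathway(s) in requested]
    if not keep:
        raise DataValidationError(f"no SNPs annotated to pathways {sorted(requested)}")
    return study.subset_snps(keep)


# ------------------------------------------------------------- combinations


@dataclass(frozen=True)
class GenotypeCombination:
    """A compound genotype condition across loci (a "carrier combination").

    Each locus carries a set of genotype codes (minor-allele counts) that
    satisfy its condition — e.g. ``{2}`` for the minor-homozygote, ``{1, 2}``
    for carriers of the minor allele. A subject matches when every locus
    condition holds. When ``cells`` is given the combination is instead the
    explicit set of joint genotype cells (used when high-risk cells do not
    factor into per-locus conditions).
    """

    loci: tuple[tuple[str, frozenset[int]], ...]
    label: str = ""
    cells: frozenset[tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        if not self.loci:
            raise DataValidationError("combination needs at least one locus")
        ids = [s for s, _ in self.loci]
        if len(set(ids)) != len(ids):
            raise DataValidationError("each SNP may appear once in a combination")
        for snp_id, cond in self.loci:
            if not cond or not set(cond) <= {0, 1, 2}:
                raise DataValidationError(
                    f"condition for {snp_id!r} must be a non-empty subset of {{0,1,2}}"
                )

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.loci)

    def default_label(self) -> str:
        def fmt(cond: frozenset[int]) -> str:
            if len(cond) == 1:
                return str(next(iter(cond)))
            if cond == CARRIER_MINOR:
                return "carrier"
            if cond == CARRIER_MAJOR:
                return "major-carrier"
            return "{" + ",".join(map(str, sorted(cond))) + "}"

        if self.cells is not None:
            cells = ";".join(
                "".join(map(str, c)) for c in sorted(self.cells)
            )
            return "/".join(self.snp_ids) + f" cells[{cells}]"
        return "/".join(f"{s}-{fmt(c)}" for s, c in self.loci)

    def evaluate(self, study: GenotypeStudy) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(matches, decidable)`` boolean vectors over subjects.

        Subjects missing a genotype at any combination locus are not
        decidable; their ``matches`` entry is False.
        """
        cols = np.stack([study.column(s) for s in self.snp_ids], axis=1)
        decidable = np.all(cols != MISSING, axis=1)
        if self.cells is not None:
            match = np.zeros(study.n_subjects, dtype=bool)
            for cell in self.cells:
                match |= np.all(cols == np.asarray(cell, dtype=np.int8), axis=1)
        else:
            match = np.ones(study.n_subjects, dtype=bool)
            for j, (_, cond) in enumerate(self.loci):
                match &= np.isin(cols[:, j], sorted(cond))
        return match & decidable, decidable


# ----------------------------------------------------------------- file I/O

_TSV_META = ["subject_id", "phenotype", "sex", "months", "event"]


def _parse_genotype_token(tok: str, row: str, col: str) -> int:
    tok = tok.strip()
    if tok in MISSING_TOKENS:
        return MISSING
    try:
        val = int(float(tok))
    except ValueError:
        raise DataValidationError(
            f"unparseable genotype {tok!r} at subject {row!r}, SNP {col!r}"
        ) from None
    if val not in (0, 1, 2):
        raise DataValidationError(
            f"genotype value {tok!r} outside {{0,1,2,missing}} at subject "
            f"{row!r}, SNP {col!r}"
        )
    return val


def recode_to_minor(study: GenotypeStudy) -> GenotypeStudy:
    """Flip columns whose counted-allele frequency exceeds 0.5 in the sample.

    Returns a study in which every column counts the sample minor allele.
    Ties at exactly 0.5 are left as coded (in PLINK files the counted allele
    name is the tie-break; plain TSVs carry no allele names).
    """
    g = study.genotypes.copy()
    for j in range(g.shape[1]):
        col = g[:, j]
        obs = col != MISSING
        if not obs.any():
            continue
        freq = col[obs].sum() / (2.0 * obs.sum())
        if freq > 0.5:
            col[obs] = 2 - col[obs]
    return GenotypeStudy(
        subject_ids=list(study.subject_ids),
        phenotype=study.phenotype.copy(),
        sex=study.sex.copy(),
        genotypes=g,
        snp_ids=list(study.snp_ids),
        survival_months=None
        if study.survival_months is None
        else study.survival_months.copy(),
        event=None if study.event is None else study.event.copy(),
    )


def read_genotype_table(
    path, dialect: str = "tsv", recode_minor: bool = False
) -> GenotypeStudy:
    """Read a genotype matrix in the plain TSV or PLINK ``.raw`` dialect.

    The TSV dialect has columns ``subject_id phenotype sex months event``
    followed by one column per SNP; the PLINK dialect has
    ``FID IID PAT MAT SEX PHENOTYPE`` followed by ``<snp>_<allele>`` columns
    with phenotype coded 1 = control, 2 = case. Missing genotype tokens
    ("NA", "", "-9", ".") map to :data:`MISSING`.

    With ``recode_minor=True`` columns are flipped so that codes count the
    within-sample minor allele (see :func:`recode_to_minor`).
    """
    if dialect == "tsv":
        study = _read_tsv(path)
    elif dialect == "plink_raw":
        study = _read_plink_raw(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    study.require_both_groups()
    return recode_to_minor(study) if recode_minor else study


def _read_tsv(path) -> GenotypeStudy:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in _TSV_META if c not in df.columns]
    if missing_cols:
        raise DataValidationError(f"genotype TSV missing columns: {missing_cols}")
    snp_cols = [c for c in df.columns if c not in _TSV_META]
    if not snp_cols:
        raise DataValidationError("genotype TSV has no SNP columns")
    n = len(df)
    geno = np.empty((n, len(snp_cols)), dtype=np.int8)
    for j, c in enumerate(snp_cols):
        geno[:, j] = [
            _parse_genotype_token(t, df["subject_id"].iat[i], c)
            for i, t in enumerate(df[c])
        ]
    months = np.array(
        [float(t) if t not in MISSING_TOKENS else np.nan for t in df["months"]]
    )
    event = np.array(
        [float(t) if t not in MISSING_TOKENS else np.nan for t in df["event"]]
    )
    if np.all(np.isnan(months)):
        months_arr, event_arr = None, None
    else:
        months_arr, event_arr = months, event
    return GenotypeStudy(
        subject_ids=list(df["subject_id"]),
        phenotype=df["phenotype"].to_numpy(dtype=object),
        sex=df["sex"].to_numpy(dtype=object),
        genotypes=geno,
        snp_ids=snp_cols,
        survival_months=months_arr,
        event=event_arr,
    )


def _read_plink_raw(path) -> GenotypeStudy:
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    required = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise DataValidationError(f"plink_raw file missing columns: {missing_cols}")
    snp_cols = [c for c in df.columns if c not in required]
    if not snp_cols:
        raise DataValidationError("plink_raw file has no SNP columns")
    # strip the counted-allele suffix rsID_A -> rsID
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    phen_map = {"1": "control", "2": "case"}
    phenotype = []
    for i, tok in enumerate(df["PHENOTYPE"]):
        if tok not in phen_map:
            raise DataValidationError(
                f"plink phenotype {tok!r} for subject {df['IID'].iat[i]!r} "
                "(expected 1=control, 2=case)"
            )
        phenotype.append(phen_map[tok])
    sex_map = {"1": "male", "2": "female"}
    sex = [sex_map.get(tok, "unknown") for tok in df["SEX"]]
    n = len(df)
    geno = np.empty((n, len(snp_cols)), dtype=np.int8)
    for j, c in enumerate(snp_cols):
        geno[:, j] = [
            _parse_genotype_token(t, df["IID"].iat[i], snp_ids[j])
            for i, t in enumerate(df[c])
        ]
    return GenotypeStudy(
        subject_ids=list(df["IID"]),
        phenotype=np.asarray(phenotype, dtype=object),
        sex=np.asarray(sex, dtype=object),
        genotypes=geno,
        snp_ids=snp_ids,
    )


def write_genotype_table(study: GenotypeStudy, path, dialect: str = "tsv") -> None:
    """Write a study in either dialect (UTF-8, tab/space-separated, deterministic)."""
    if dialect == "tsv":
        _write_tsv(study, path)
    elif dialect == "plink_raw":
        _write_plink_raw(study, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _fmt_geno(v: int) -> str:
    return "NA" if v == MISSING else str(int(v))


def _write_tsv(study: GenotypeStudy, path) -> None:
    cols: dict[str, list] = {
        "subject_id": study.subject_ids,
        "phenotype": list(study.phenotype),
        "sex": list(study.sex),
    }
    if study.survival_months is None:
        cols["months"] = ["NA"] * study.n_subjects
        cols["event"] = ["NA"] * study.n_subjects
    else:
        cols["months"] = [
            "NA" if np.isnan(v) else format(v, "g") for v in study.survival_months
        ]
        cols["event"] = [
            "NA" if np.isnan(v) else str(int(v)) for v in study.event
        ]
    for j, snp in enumerate(study.snp_ids):
        cols[snp] = [_fmt_geno(v) for v in study.genotypes[:, j]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _write_plink_raw(study: GenotypeStudy, path) -> None:
    sex_map = {"male": "1", "female": "2", "unknown": "0"}
    phen_map = {"control": "1", "case": "2"}
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + [
        f"{s}_A" for s in study.snp_ids
    ]
    lines = [" ".join(header)]
    for i, sid in enumerate(study.subject_ids):
        row = [
            sid,
            sid,
            "0",
            "0",
            sex_map[study.sex[i]],
            phen_map[study.phenotype[i]],
        ] + [_fmt_geno(v) for v in study.genotypes[i]]
        lines.append(" ".join(row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
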