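"""GWAS summary-statistic ingestion and harmonization.

This module reads per-SNP association records from delimited text files,
converts Z-scores to beta/SE on the allele-frequency scale, aligns outcome
effects to the exposure effect allele (including strand flips and
palindrome policy), performs LD clumping against a user-supplied pairwise
r-squared table, and applies the instrument-selection filters used in
two-sample Mendelian randomization:

* genome-wide significance of the SNP-exposure association,
* independence (pairwise r-squared below a threshold within a window),
* exclusion of instruments with a genome-wide-significant association
  with the *outcome*, which would violate the exclusion-restriction
  assumption (the instrument may act on the outcome only through the
  exposure).

Harmonized instruments are carried as a :class:`pandas.DataFrame` with
the column contract documented on :func:`harmonize`; individual
associations are :class:`SummaryStatRecord` dataclasses.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DegenerateFrequencyError,
    SumstatsError,
    UnsupportedAlleleError,
)

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: Default header names, following common GWAS summary-statistic exports.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
    "zscore": "Z",
}

MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval")

#: Columns of a harmonized-instrument frame, in canonical order.
INSTRUMENT_COLUMNS = [
    "snp_id",
    "eaf",
    "beta_exp",
    "se_exp",
    "p_exp",
    "beta_out",
    "se_out",
    "p_out",
    "palindromic",
    "flipped",
]


@dataclass
class SummaryStatRecord:
    """One SNP's association with one trait in one study.

    ``beta`` is the per-effect-allele effect in the study's trait units
    (for a Z-score GWAS, the units produced by :func:`z_to_beta`); ``se``
    its standard error.  ``zscore`` may be the primary datum when the
    source GWAS reports only standardized effects.
    """

    snp_id: str
    chrom: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    pos: int | None = None
    zscore: float | None = None
    n: float | None = None

    def problems(self) -> list[str]:
        """Invariant violations, as human-readable strings (empty = valid)."""
        out = []
        if not (0.0 < self.eaf < 1.0):
            out.append(f"eaf {self.eaf!r} outside (0, 1)")
        if not (self.se > 0):
            out.append(f"se {self.se!r} not positive")
        if not (0.0 < self.pval <= 1.0):
            out.append(f"pval {self.pval!r} outside (0, 1]")
        if self.effect_allele == self.other_allele:
            out.append(f"effect and other allele both {self.effect_allele!r}")
        if self.zscore is not None and self.zscore != 0:
            if abs(self.beta / self.se - self.zscore) > 0.01 * abs(self.zscore):
                out.append(
                    f"beta/se {self.beta / self.se:.4f} disagrees with zscore {self.zscore}"
                )
        return out


def _coerce(value: str, kind: type, field_name: str):
    if value is None or value == "" or value.upper() in ("NA", "NAN", "."):
        return None
    try:
        return kind(value) if kind is not int else int(float(value))
    except ValueError as exc:
        raise ValueError(f"unparseable {field_name} {value!r}") from exc


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.readline()
    return "\t" if sample.count("\t") >= sample.count(",") else ","


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    strict: bool = False,
) -> list[SummaryStatRecord]:
    """Read summary statistics from a TSV/CSV file.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from record field names to header names; unspecified
        fields fall back to :data:`DEFAULT_COLUMN_MAP`.
    delimiter
        ``"\\t"`` or ``","``; auto-detected from the header when None.
    strict
        When True, any invalid row raises :class:`SumstatsError`;
        otherwise invalid rows are dropped with a logged, row-numbered
        diagnostic.

    Returns
    -------
    list of SummaryStatRecord
        One record per valid data row, allele strings upper-cased.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    delim = delimiter or _sniff_delimiter(path)

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [cmap[f] for f in MANDATORY_FIELDS if cmap[f] not in header]
        if missing:
            raise ConfigurationError(
                f"{path}: mandatory column(s) {missing} absent from header {header}"
            )
        present = {f: cmap[f] for f in cmap if cmap[f] in header}

        records: list[SummaryStatRecord] = []
        row_errors: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = SummaryStatRecord(
                    snp_id=row[present["snp_id"]].strip(),
                    chrom=str(row[present["chrom"]]).strip() if "chrom" in present else "NA",
                    effect_allele=row[present["effect_allele"]].strip().upper(),
                    other_allele=row[present["other_allele"]].strip().upper(),
                    eaf=_coerce(row[present["eaf"]], float, "eaf"),
                    beta=_coerce(row[present["beta"]], float, "beta"),
                    se=_coerce(row[present["se"]], float, "se"),
                    pval=_coerce(row[present["pval"]], float, "pval"),
                    pos=_coerce(row[present["pos"]], int, "pos") if "pos" in present else None,
                    zscore=_coerce(row[present["zscore"]], float, "zscore")
                    if "zscore" in present
                    else None,
                    n=_coerce(row[present["n"]], float, "n") if "n" in present else None,
                )
            except (ValueError, TypeError) as exc:
                row_errors.append(f"{path.name} row {lineno}: {exc}")
                continue
            bad = rec.problems()
            if bad:
                row_errors.append(f"{path.name} row {lineno} ({rec.snp_id}): " + "; ".join(bad))
                continue
            records.append(rec)

    if row_errors:
        if strict:
            raise SumstatsError(
                f"{len(row_errors)} invalid row(s) in {path}", row_errors=row_errors
            )
        for msg in row_errors:
            logger.warning("rejected: %s", msg)
    logger.info("read %d records from %s (%d rejected)", len(records), path, len(row_errors))
    return records


def write_sumstats(
    records: Iterable[SummaryStatRecord],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> None:
    """Write records to a delimited file; floats use repr precision so a
    read-back round-trips every numeric field exactly."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    order = [f.name for f in fields(SummaryStatRecord)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([cmap[name] for name in order])
        for rec in records:
            writer.writerow(
                ["" if getattr(rec, name) is None else repr(getattr(rec, name))
                 if isinstance(getattr(rec, name), float) else getattr(rec, name)
                 for name in order]
            )


def z_to_beta(zscore: float, eaf: float, n: float) -> tuple[float, float]:
    """Convert a Z-score association to (beta, se) on the per-allele scale.

    For a standardized trait, ``beta = z / sqrt(2 p (1-p) (n + z^2))`` and
    ``se = 1 / sqrt(2 p (1-p) (n + z^2))``, so ``beta / se`` equals the
    Z-score exactly.
    """
    if not (0.0 < eaf < 1.0):
        raise DegenerateFrequencyError(f"eaf must lie strictly in (0, 1); got {eaf}")
    if n <= 0:
        raise ValueError(f"sample size must be positive; got {n}")
    denom = math.sqrt(2.0 * eaf * (1.0 - eaf) * (n + zscore**2))
    return zscore / denom, 1.0 / denom


def detect_palindrome(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is A/T or C/G (strand-ambiguous)."""
    a, b = effect_allele.upper(), other_allele.upper()
    for x in (a, b):
        if x not in VALID_ALLELES:
            raise UnsupportedAlleleError(f"allele {x!r} not one of A/C/G/T")
    return frozenset((a, b)) in PALINDROMIC_PAIRS


def _align(exp: SummaryStatRecord, out: SummaryStatRecord) -> tuple[SummaryStatRecord, bool] | None:
    """Return the outcome record re-expressed on the exposure's effect
    allele, with a flag for whether its sign was flipped; None when the
    allele sets cannot be reconciled even after strand complementing."""
    e = (exp.effect_allele, exp.other_allele)
    candidates = [
        (out.effect_allele, out.other_allele, out),
        (
            COMPLEMENT[out.effect_allele],
            COMPLEMENT[out.other_allele],
            out,
        ),
    ]
    for ea, oa, rec in candidates:
        if (ea, oa) == e:
            return rec, False
        if (oa, ea) == e:
            flipped = replace(rec, beta=-rec.beta, eaf=1.0 - rec.eaf,
                              zscore=None if rec.zscore is None else -rec.zscore,
                              effect_allele=exp.effect_allele, other_allele=exp.other_allele)
            return flipped, True
    return None


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindrome_policy: str = "drop",
    ambiguous_eaf: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Merge exposure and outcome associations into harmonized instruments.

    Outcome effects are aligned to the exposure effect allele: when the
    outcome's effect allele matches the exposure's *other* allele (on
    either strand), the outcome beta sign is flipped and its frequency
    complemented.  SNPs absent from either study are dropped with a
    logged count, as are SNPs whose allele pairs cannot be reconciled.

    Palindromic (A/T, C/G) SNPs cannot be strand-resolved from alleles
    alone; policy ``"drop"`` (default) removes them, ``"infer"`` aligns
    them by allele frequency and drops those with exposure or outcome EAF
    inside the ``ambiguous_eaf`` band, ``"keep"`` assumes both studies
    report the same strand.

    Returns
    -------
    pandas.DataFrame
        Columns :data:`INSTRUMENT_COLUMNS`; one row per retained SNP,
        exposure input order preserved.
    """
    if palindrome_policy not in ("drop", "infer", "keep"):
        raise ConfigurationError(f"unknown palindrome policy {palindrome_policy!r}")
    out_by_id = {r.snp_id: r for r in outcome}
    rows = []
    n_missing = n_palindromic = n_irreconcilable = 0
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            n_missing += 1
            continue
        pal = detect_palindrome(exp.effect_allele, exp.other_allele)
        if pal:
            if palindrome_policy == "drop":
                n_palindromic += 1
                logger.debug("dropping palindromic SNP %s", exp.snp_id)
                continue
            if palindrome_policy == "infer":
                lo, hi = ambiguous_eaf
                if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
                    n_palindromic += 1
                    logger.debug("dropping ambiguous palindromic SNP %s", exp.snp_id)
                    continue
                # Frequencies on opposite sides of 0.5 mean the two studies
                # report opposite strands: flip the outcome effect.
                same_side = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
                aligned, flipped = (out, False) if same_side else (
                    replace(out, beta=-out.beta, eaf=1.0 - out.eaf), True
                )
                rows.append((exp, aligned, pal, flipped))
                continue
            # "keep": fall through to literal allele matching
        res = _align(exp, out)
        if res is None:
            n_irreconcilable += 1
            logger.warning(
                "dropping %s: alleles %s/%s vs %s/%s irreconcilable",
                exp.snp_id, exp.effect_allele, exp.other_allele,
                out.effect_allele, out.other_allele,
            )
            continue
        aligned, flipped = res
        rows.append((exp, aligned, pal, flipped))
    logger.info(
        "harmonized %d instruments (%d absent from outcome, %d palindromic dropped, "
        "%d irreconcilable)", len(rows), n_missing, n_palindromic, n_irreconcilable,
    )
    return pd.DataFrame(
        [
            {
                "snp_id": e.snp_id,
                "eaf": e.eaf,
                "beta_exp": e.beta,
                "se_exp": e.se,
                "p_exp": e.pval,
                "beta_out": o.beta,
                "se_out": o.se,
                "p_out": o.pval,
                "palindromic": pal,
                "flipped": flipped,
            }
            for e, o, pal, flipped in rows
        ],
        columns=INSTRUMENT_COLUMNS,
    )


@dataclass
class LdTable:
    """Symmetric pairwise linkage-disequilibrium (r-squared) lookup.

    Missing pairs are treated as independent (r-squared 0) with a logged
    warning, the pragmatic default when the LD reference panel does not
    cover every pair.
    """

    _r2: dict[frozenset, float] = field(default_factory=dict)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 {r2} outside [0, 1]")
        self._r2[frozenset((a, b))] = r2

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = frozenset((a, b))
        if key not in self._r2:
            logger.warning("LD pair (%s, %s) absent from table; assuming independence", a, b)
            return 0.0
        return self._r2[key]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return a == b or frozenset((a, b)) in self._r2

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdTable":
        """Load from a three-column (snp_a, snp_b, r2) TSV with header."""
        table = cls()
        frame = pd.read_csv(path, sep="\t")
        for a, b, r2 in frame.itertuples(index=False):
            table.set(str(a), str(b), float(r2))
        return table

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("snp_a\tsnp_b\tr2\n")
            for key, r2 in sorted(self._r2.items(), key=lambda kv: sorted(kv[0])):
                pair = sorted(key) if len(key) == 2 else [next(iter(key))] * 2
                fh.write(f"{pair[0]}\t{pair[1]}\t{r2!r}\n")


def ld_clump(
    records: Sequence[SummaryStatRecord],
    ld: LdTable,
    r2_max: float = 0.3,
    window: float | None = 10_000_000,
) -> list[SummaryStatRecord]:
    """Greedy LD clumping: scan SNPs by ascending p-value, retaining each
    one iff its r-squared with every already-retained SNP within ``window``
    base pairs (same chromosome) is below ``r2_max``.

    Output preserves the input ordering.  ``window=None`` compares all
    pairs regardless of position (positions then not required).
    """
    if window is not None and any(r.pos is None for r in records):
        missing = [r.snp_id for r in records if r.pos is None]
        raise ConfigurationError(
            f"LD clumping with a finite window needs positions; missing for {missing}"
        )
    order = sorted(range(len(records)), key=lambda i: (records[i].pval, records[i].snp_id))
    kept_idx: list[int] = []
    for i in order:
        rec = records[i]
        ok = True
        for j in kept_idx:
            other = records[j]
            if window is not None:
                if rec.chrom != other.chrom or abs(rec.pos - other.pos) > window:
                    continue
            if ld.get(rec.snp_id, other.snp_id) >= r2_max:
                ok = False
                logger.debug("clumped %s (r2 with %s >= %g)", rec.snp_id, other.snp_id, r2_max)
                break
        if ok:
            kept_idx.append(i)
    kept_idx.sort()
    logger.info("LD clumping kept %d of %d SNPs", len(kept_idx), len(records))
    return [records[i] for i in kept_idx]


def filter_significant(
    records: Sequence[SummaryStatRecord], p_threshold: float = 5e-8
) -> list[SummaryStatRecord]:
    """Keep SNPs whose exposure association reaches ``p < p_threshold``
    (genome-wide significance by default)."""
    kept = [r for r in records if r.pval < p_threshold]
    logger.info("significance filter kept %d of %d SNPs", len(kept), len(records))
    return kept


def exclude_outcome_associated(
    instruments: pd.DataFrame, p_threshold: float = 5e-8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split instruments into (kept, excluded) by the outcome-association
    rule: an instrument associated with the outcome at ``p_out <
    p_threshold`` plausibly acts on the outcome through a pathway other
    than the exposure and is removed."""
    if instruments.empty:
        return instruments.copy(), instruments.copy()
    mask = instruments["p_out"] < p_threshold
    excluded = instruments[mask].reset_index(drop=True)
    kept = instruments[~mask].reset_index(drop=True)
    for snp in excluded["snp_id"]:
        logger.info("excluding %s: outcome association below %g", snp, p_threshold)
    return kept, excluded


def records_to_frame(records: Sequence[SummaryStatRecord]) -> pd.DataFrame:
    """Tabular view of a record list (one column per dataclass field)."""
    return pd.DataFrame([vars(r) for r in records])


def write_instruments(instruments: pd.DataFrame, path: str | Path) -> None:
    """Serialize a harmonized-instrument frame as TSV (repr-precision floats)."""
    instruments.to_csv(path, sep="\t", index=False, float_format=None)


def read_instruments(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in INSTRUMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"{path}: instrument columns {missing} absent")
    return frame[INSTRUMENT_COLUMNS]
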