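"""Readers and writers for the pipeline's plain-text formats.

Pedigrees use a FAM-like tab-separated dialect: columns family_id,
individual_id, father_id, mother_id, sex, zygosity, and optionally sampled
(1/0) and age. "0" marks a missing parent; sex is 1 = male, 2 = female,
0 = unknown on disk (analyses recode to 0 = male, 1 = female). Genotype
tables are wide TSV (individual_id + one column per variant) holding either
allele pairs like ``A/G`` or 0/1/2 codes, with ``NA`` for missing. Activity
tables are CSV with one row per individual x wave x activity.

Writers prepend self-describing ``#`` header lines (package version, seed,
config hash); readers validate and report every offending line number rather
than coercing.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype import GenotypeVector, VariantSpec, code_snp, code_vntr
from .pedigree import FEMALE, MALE, Individual, Pedigree
from .phenotype import ActivityRecord

_SEX_TO_DISK = {MALE: "1", FEMALE: "2", None: "0"}
_SEX_FROM_DISK = {"1": MALE, "2": FEMALE, "0": None}

PEDIGREE_COLUMNS = ("family_id", "individual_id", "father_id", "mother_id",
                    "sex", "zygosity", "sampled", "age")


class ParseError(ValueError):
    """Malformed input file; the message lists every offending line."""


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(seed: Optional[int], config: Optional[Mapping]) -> list[str]:
    lines = [f"# exergen {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    return lines


def write_report(path: str | Path, table: pd.DataFrame,
                 seed: Optional[int] = None,
                 config: Optional[Mapping] = None,
                 float_format: str = "%.6g") -> None:
    """Write a TSV report with a self-describing comment header."""
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(seed, config):
            fh.write(line + "\n")
        table.to_csv(fh, sep="\t", index=False, float_format=float_format,
                     na_rep="NA")


def write_pedigree(path: str | Path, pedigree: Pedigree,
                   seed: Optional[int] = None,
                   config: Optional[Mapping] = None) -> None:
    rows = []
    for ind in pedigree.individuals:
        rows.append({
            "family_id": ind.family_id,
            "individual_id": ind.individual_id,
            "father_id": ind.father_id or "0",
            "mother_id": ind.mother_id or "0",
            "sex": _SEX_TO_DISK[ind.sex],
            "zygosity": ind.zygosity,
            "sampled": int(ind.in_analysis),
            "age": "NA" if ind.age is None else ind.age,
        })
    write_report(path, pd.DataFrame(rows, columns=PEDIGREE_COLUMNS),
                 seed=seed, config=config)


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a FAM-like TSV; collects all row-level errors before raising."""
    path = Path(path)
    individuals: list[Individual] = []
    errors: list[str] = []
    with path.open() as fh:
        lines = fh.readlines()
    header_cols: Optional[list[str]] = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header_cols is None and fields[0] == "family_id":
            header_cols = fields
            continue
        if len(fields) < 6:
            errors.append(f"line {lineno}: expected >= 6 tab-separated columns")
            continue
        fam, iid, father, mother, sex_code, zyg = fields[:6]
        if sex_code not in _SEX_FROM_DISK:
            errors.append(f"line {lineno}: bad sex code {sex_code!r} (use 0/1/2)")
            continue
        if zyg not in ("MZ", "DZ", "none"):
            errors.append(f"line {lineno}: bad zygosity {zyg!r}")
            continue
        sampled = True
        if len(fields) >= 7 and fields[6] != "":
            sampled = fields[6] == "1"
        age = None
        if len(fields) >= 8 and fields[7] not in ("", "NA"):
            try:
                age = float(fields[7])
            except ValueError:
                errors.append(f"line {lineno}: bad age {fields[7]!r}")
                continue
        individuals.append(Individual(
            individual_id=iid, family_id=fam,
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            sex=_SEX_FROM_DISK[sex_code], zygosity=zyg,
            age=age, in_analysis=sampled,
        ))
    if errors:
        raise ParseError(f"{path}: " + "; ".join(errors))
    try:
        return Pedigree(individuals)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_genotypes(path: str | Path, ids: Sequence[str],
                    genotypes: Mapping[str, GenotypeVector],
                    seed: Optional[int] = None,
                    config: Optional[Mapping] = None) -> None:
    """Wide 0/1/2-coded genotype TSV; missing codes written as NA."""
    table = pd.DataFrame({"individual_id": list(ids)})
    for vid, gv in genotypes.items():
        if len(gv) != len(ids):
            raise ParseError(f"{vid}: genotype length differs from id list")
        codes = gv.codes
        col = [("NA" if np.isnan(c) else (c if gv.dosage else int(c)))
               for c in codes]
        table[vid] = col
    write_report(path, table, seed=seed, config=config)


def read_genotypes(path: str | Path,
                   specs: Mapping[str, VariantSpec]) -> dict[str, GenotypeVector]:
    """Read a wide genotype TSV of allele pairs (``A/G``) or 0/1/2 codes.

    Columns without a matching :class:`VariantSpec` raise; per-cell problems
    are reported with line numbers.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                        keep_default_na=False)
    if "individual_id" not in table.columns:
        raise ParseError(f"{path}: missing required column individual_id")
    unknown = [c for c in table.columns if c != "individual_id" and c not in specs]
    if unknown:
        raise ParseError(f"{path}: columns without a variant spec: {unknown}")
    out: dict[str, GenotypeVector] = {}
    errors: list[str] = []
    for vid in (c for c in table.columns if c != "individual_id"):
        spec = specs[vid]
        values = table[vid].tolist()
        if any("/" in v for v in values if v not in ("NA", "")):
            pairs = []
            for i, v in enumerate(values):
                if v in ("NA", ""):
                    pairs.append(None)
                elif "/" in v:
                    pairs.append(tuple(v.split("/", 1)))
                else:
                    errors.append(f"line {i + 2}: {vid}: expected allele pair, got {v!r}")
                    pairs.append(None)
            coder = code_snp if spec.kind == "snp" else code_vntr
            try:
                out[vid] = coder(pairs, spec)
            except Exception as exc:
                errors.append(f"{vid}: {exc}")
        else:
            codes = np.full(len(values), np.nan)
            for i, v in enumerate(values):
                if v in ("NA", ""):
                    continue
                try:
                    codes[i] = float(v)
                except ValueError:
                    errors.append(f"line {i + 2}: {vid}: bad code {v!r}")
            dosage = bool(np.any(codes[~np.isnan(codes)] !=
                                 np.round(codes[~np.isnan(codes)])))
            try:
                out[vid] = GenotypeVector(spec, codes, dosage=dosage)
            except Exception as exc:
                errors.append(f"{vid}: {exc}")
    if errors:
        raise ParseError(f"{path}: " + "; ".join(errors))
    return out


ACTIVITY_COLUMNS = ("individual_id", "survey_wave", "age_at_survey",
                    "activity_name", "met_value", "years_participated",
                    "months_per_year", "times_per_week", "minutes_per_session",
                    "leisure_flag", "injured_at_survey")


def read_activities(path: str | Path) -> list[ActivityRecord]:
    """Read an activity CSV into validated :class:`ActivityRecord` rows."""
    path = Path(path)
    table = pd.read_csv(path, comment="#")
    missing = sorted(set(ACTIVITY_COLUMNS) - {"met_value"} - set(table.columns))
    if missing:
        raise ParseError(f"{path}: missing columns: {missing}")
    extra = sorted(set(table.columns) - set(ACTIVITY_COLUMNS))
    if extra:
        raise ParseError(f"{path}: unexpected columns: {extra}")
    records: list[ActivityRecord] = []
    errors: list[str] = []
    for i, row in table.iterrows():
        met = row.get("met_value")
        try:
            records.append(ActivityRecord(
                individual_id=str(row["individual_id"]),
                survey_wave=str(row["survey_wave"]),
                age_at_survey=float(row["age_at_survey"]),
                activity_name=str(row["activity_name"]),
                met_value=None if met is None or pd.isna(met) else float(met),
                years_participated=float(row["years_participated"]),
                months_per_year=float(row["months_per_year"]),
                times_per_week=float(row["times_per_week"]),
                minutes_per_session=float(row["minutes_per_session"]),
                leisure_flag=bool(row["leisure_flag"]),
                injured_at_survey=bool(row["injured_at_survey"]),
            ))
        except Exception as exc:
            errors.append(f"line {i + 2}: {exc}")
    if errors:
        raise ParseError(f"{path}: " + "; ".join(errors))
    return records


def read_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: expected a key-value mapping")
    return cfg
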