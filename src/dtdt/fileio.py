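"""Readers/writers for pedigree, map, dosage and results files; trio extraction.

Pedigrees use the classic whitespace-delimited LINKAGE/MERLIN layout: one row
per individual with leading columns (family, individual, father, mother, sex
[, affection]) followed by two allele columns per marker, allele code 0 =
missing.  Marker order comes from a companion file, either a MERLIN-style
``.dat`` (lines ``M <name>``, plus optional ``A <name>`` for the affection
column) or a 4-column map (chromosome, name, genetic cM, physical bp).

Dosage tables are tab-separated with a header ``individual  marker  p11  p12
p22`` — the long layout; a documented adapter accepts a wide per-individual
layout with three columns per marker.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from .simulate import SimulatedTrio

__all__ = [
    "PedigreeRecord",
    "TrioRecord",
    "PedParseError",
    "AFFECTION_CODES",
    "read_pedfile",
    "write_pedfile",
    "read_mapfile",
    "write_mapfile",
    "read_dosage_table",
    "write_dosage_table",
    "read_wide_dosage_table",
    "extract_trios",
    "simulated_trios_to_pedigree",
    "write_results_table",
    "read_results_table",
]

# LINKAGE affection-status convention
AFFECTION_CODES: Dict[int, str] = {0: "unknown", -9: "unknown", 1: "unaffected", 2: "affected"}

_DAT_CODES = {"M", "A", "T", "C", "S", "S2", "E"}

Genotype = Optional[Tuple[int, int]]


class PedParseError(ValueError):
    """Malformed pedigree/companion file; the message names the offending line."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: identifiers, sex, affection status and marker genotypes.

    ``genotypes`` is one allele-pair tuple per marker, ``None`` when missing
    (allele code 0 in the file); ``affection`` is one of ``unknown``,
    ``unaffected``, ``affected``.
    """

    family_id: str
    individual_id: str
    father_id: str
    mother_id: str
    sex: int
    affection: str = "unknown"
    genotypes: Tuple[Genotype, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        if self.affection not in ("unknown", "unaffected", "affected"):
            raise ValueError(f"bad affection status {self.affection!r}")
        for g in self.genotypes:
            if g is not None and (g[0] < 1 or g[1] < 1):
                raise ValueError(f"allele codes must be positive, got {g!r}")

    @property
    def is_founder(self) -> bool:
        return self.father_id == "0" and self.mother_id == "0"


@dataclass(frozen=True)
class TrioRecord:
    """An affected child with both parents identified in its family."""

    family_id: str
    child_id: str
    father_id: str
    mother_id: str
    child_affected: bool
    father_ms_genotyped: bool
    mother_ms_genotyped: bool

    def __post_init__(self) -> None:
        if not self.child_affected:
            raise ValueError("a trio's child must be affected")
        if not (self.father_ms_genotyped or self.mother_ms_genotyped):
            raise ValueError("at least one parent must be linkage-genotyped")


def _nonempty_lines(path: Union[str, Path]) -> List[Tuple[int, List[str]]]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            out.append((lineno, line.split()))
    return out


def _parse_companion(path: Union[str, Path]) -> Tuple[List[str], bool]:
    """Marker names and whether an affection column is declared.

    Accepts a MERLIN ``.dat`` (two-token ``<code> <name>`` lines) or a
    3/4-column map file.
    """
    lines = _nonempty_lines(path)
    if not lines:
        raise PedParseError(f"{path}: companion file is empty")
    is_dat = all(len(f) == 2 and f[0].upper() in _DAT_CODES for _, f in lines)
    if is_dat:
        markers = [f[1] for _, f in lines if f[0].upper() == "M"]
        has_affection = any(f[0].upper() == "A" for _, f in lines)
        return markers, has_affection
    markers = []
    for lineno, f in lines:
        if len(f) not in (3, 4):
            raise PedParseError(f"{path}:{lineno}: expected a dat line or 3/4 map columns")
        markers.append(f[1])
    # map files carry no phenotype declaration; rely on ped column count
    return markers, False


def read_pedfile(
    ped_path: Union[str, Path],
    dat_or_map_path: Union[str, Path],
    affection_codes: Optional[Dict[int, str]] = None,
) -> Tuple[List[PedigreeRecord], List[str]]:
    """Parse a LINKAGE/MERLIN ped file with its companion dat/map file.

    The number of leading columns (5 without, 6 with an affection column) is
    inferred from the row length against the companion's marker count.
    Raises :class:`PedParseError` on ragged rows, allele-count mismatches or
    duplicate individual ids, naming the line.
    """
    codes = dict(AFFECTION_CODES if affection_codes is None else affection_codes)
    markers, dat_affection = _parse_companion(dat_or_map_path)
    n_alleles = 2 * len(markers)
    records: List[PedigreeRecord] = []
    seen: Set[Tuple[str, str]] = set()
    for lineno, f in _nonempty_lines(ped_path):
        if len(f) == 6 + n_alleles:
            lead = 6
        elif len(f) == 5 + n_alleles and not dat_affection:
            lead = 5
        else:
            raise PedParseError(
                f"{ped_path}:{lineno}: row has {len(f)} fields; expected "
                f"{5 + n_alleles} or {6 + n_alleles} for {len(markers)} markers"
            )
        fam, ind, fa, mo = f[0], f[1], f[2], f[3]
        if (fam, ind) in seen:
            raise PedParseError(f"{ped_path}:{lineno}: duplicate individual {fam}:{ind}")
        seen.add((fam, ind))
        try:
            sex = int(f[4])
        except ValueError as exc:
            raise PedParseError(f"{ped_path}:{lineno}: bad sex code {f[4]!r}") from exc
        affection = "unknown"
        if lead == 6:
            try:
                affection = codes[int(f[5])]
            except (KeyError, ValueError) as exc:
                raise PedParseError(
                    f"{ped_path}:{lineno}: bad affection code {f[5]!r}"
                ) from exc
        genotypes: List[Genotype] = []
        for k in range(len(markers)):
            a_str, b_str = f[lead + 2 * k], f[lead + 2 * k + 1]
            try:
                a, b = int(a_str), int(b_str)
            except ValueError as exc:
                raise PedParseError(
                    f"{ped_path}:{lineno}: non-integer allele {a_str!r}/{b_str!r}"
                ) from exc
            if a < 0 or b < 0:
                raise PedParseError(f"{ped_path}:{lineno}: negative allele code")
            genotypes.append(None if a == 0 or b == 0 else (a, b))
        records.append(
            PedigreeRecord(fam, ind, fa, mo, sex, affection, tuple(genotypes))
        )
    _check_parent_refs(records)
    return records, markers


def _check_parent_refs(records: Sequence[PedigreeRecord]) -> None:
    by_family: Dict[str, Set[str]] = {}
    for r in records:
        by_family.setdefault(r.family_id, set()).add(r.individual_id)
    # non-founder parent ids may legitimately be absent (marry-ins without
    # records are skipped at trio extraction), so only self-parenting is fatal
    for r in records:
        if r.individual_id in (r.father_id, r.mother_id):
            raise PedParseError(
                f"individual {r.family_id}:{r.individual_id} is its own parent"
            )


_AFFECTION_TO_CODE = {"unknown": 0, "unaffected": 1, "affected": 2}


def write_pedfile(
    records: Sequence[PedigreeRecord],
    markers: Sequence[str],
    ped_path: Union[str, Path],
    dat_path: Union[str, Path],
) -> None:
    """Write ped + dat files (inverse of :func:`read_pedfile`).

    Always emits the 6-column leading layout (affection included) and a dat
    with an ``A`` line followed by one ``M`` line per marker.
    """
    markers = list(markers)
    for r in records:
        if len(r.genotypes) != len(markers):
            raise ValueError(
                f"individual {r.family_id}:{r.individual_id} has "
                f"{len(r.genotypes)} genotypes for {len(markers)} markers"
            )
    with open(dat_path, "w") as fh:
        fh.write("A affection\n")
        for m in markers:
            fh.write(f"M {m}\n")
    with open(ped_path, "w") as fh:
        for r in records:
            fields = [
                r.family_id,
                r.individual_id,
                r.father_id,
                r.mother_id,
                str(r.sex),
                str(_AFFECTION_TO_CODE[r.affection]),
            ]
            for g in r.genotypes:
                fields += ["0", "0"] if g is None else [str(g[0]), str(g[1])]
            fh.write(" ".join(fields) + "\n")


def read_mapfile(path: Union[str, Path]) -> pd.DataFrame:
    """Read a 4-column map (chromosome, name, gm cM, pm bp) into a frame."""
    rows = []
    for lineno, f in _nonempty_lines(path):
        if len(f) != 4:
            raise PedParseError(f"{path}:{lineno}: expected 4 map columns, got {len(f)}")
        try:
            rows.append((f[0], f[1], float(f[2]), int(f[3])))
        except ValueError as exc:
            raise PedParseError(f"{path}:{lineno}: bad numeric field") from exc
    return pd.DataFrame(rows, columns=["chromosome", "name", "gm", "pm"])


def write_mapfile(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(f"{row.chromosome} {row.name} {row.gm:.6f} {int(row.pm)}\n")


# dosage rows are renormalized when their sum is within this distance of 1
# and rejected beyond it
DOSAGE_SUM_TOL = 0.01 + 1e-12


def read_dosage_table(path: Union[str, Path]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-layout dosage TSV; returns (accepted rows, rejection report).

    Each accepted row's probability triple is renormalized to sum exactly
    to 1; rows whose sum deviates from 1 by more than ``DOSAGE_SUM_TOL`` are
    rejected and listed in the report with their row number and sum.
    """
    frame = pd.read_csv(path, sep="\t")
    required = ["individual", "marker", "p11", "p12", "p22"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise PedParseError(f"{path}: dosage table missing columns {missing}")
    probs = frame[["p11", "p12", "p22"]].to_numpy(dtype=float)
    sums = probs.sum(axis=1)
    bad = (abs(sums - 1.0) > DOSAGE_SUM_TOL) | (probs < 0).any(axis=1)
    report = pd.DataFrame(
        {
            "row": frame.index[bad] + 2,  # 1-based file line incl. header
            "individual": frame.loc[bad, "individual"],
            "marker": frame.loc[bad, "marker"],
            "sum": sums[bad],
        }
    ).reset_index(drop=True)
    accepted = frame.loc[~bad].copy()
    accepted[["p11", "p12", "p22"]] = probs[~bad] / sums[~bad, None]
    return accepted.reset_index(drop=True), report


def write_dosage_table(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_wide_dosage_table(path: Union[str, Path]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Adapter for the wide per-individual dosage layout.

    Expects a TSV whose header is ``individual`` followed by three columns per
    marker named ``<marker>:p11``, ``<marker>:p12``, ``<marker>:p22``; melts
    into the long layout and applies the same normalization policy as
    :func:`read_dosage_table`.
    """
    wide = pd.read_csv(path, sep="\t")
    if wide.columns[0] != "individual":
        raise PedParseError(f"{path}: first column must be 'individual'")
    markers: List[str] = []
    for col in wide.columns[1:]:
        if ":" not in col:
            raise PedParseError(f"{path}: bad wide dosage column {col!r}")
        name, _ = col.rsplit(":", 1)
        if name not in markers:
            markers.append(name)
    rows = []
    for _, r in wide.iterrows():
        for m in markers:
            rows.append(
                (r["individual"], m, r[f"{m}:p11"], r[f"{m}:p12"], r[f"{m}:p22"])
            )
    long = pd.DataFrame(rows, columns=["individual", "marker", "p11", "p12", "p22"])
    buf = io.StringIO()
    long.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return read_dosage_table(buf)  # type: ignore[arg-type]


def extract_trios(
    pedigrees: Sequence[PedigreeRecord],
    ms_genotyped: Set[Tuple[str, str]],
) -> Tuple[List[TrioRecord], Dict[str, int]]:
    """Extract every eligible trio: one per affected child whose parents are
    both present in the family and at least one of whom is linkage-genotyped.

    ``ms_genotyped`` holds (family_id, individual_id) pairs.  Multiple
    affected siblings yield multiple trios sharing the same parents.  Returns
    (trios, report) where the report counts children skipped per reason.
    """
    by_family: Dict[str, Dict[str, PedigreeRecord]] = {}
    for r in pedigrees:
        by_family.setdefault(r.family_id, {})[r.individual_id] = r
    trios: List[TrioRecord] = []
    report = {"not_affected": 0, "parent_missing": 0, "no_ms_parent": 0}
    for r in pedigrees:
        if r.is_founder and r.affection != "affected":
            continue
        if r.affection != "affected":
            report["not_affected"] += 1
            continue
        fam = by_family[r.family_id]
        if r.father_id == "0" or r.mother_id == "0" or r.father_id not in fam or r.mother_id not in fam:
            report["parent_missing"] += 1
            continue
        fa_ms = (r.family_id, r.father_id) in ms_genotyped
        mo_ms = (r.family_id, r.mother_id) in ms_genotyped
        if not (fa_ms or mo_ms):
            report["no_ms_parent"] += 1
            continue
        trios.append(
            TrioRecord(
                family_id=r.family_id,
                child_id=r.individual_id,
                father_id=r.father_id,
                mother_id=r.mother_id,
                child_affected=True,
                father_ms_genotyped=fa_ms,
                mother_ms_genotyped=mo_ms,
            )
        )
    return trios, report


_SNP_ALLELES = {0: (1, 1), 1: (1, 2), 2: (2, 2)}


def simulated_trios_to_pedigree(
    trios: Sequence[SimulatedTrio],
) -> Tuple[List[PedigreeRecord], List[str]]:
    """Serialize simulated trios as nuclear families with two markers.

    Markers are ``ms1`` (the informative microsatellite, typed in everyone)
    and ``snp1`` (typed in the child only — the parents are the individuals
    whose dosages the inference step must supply).  Children are affected;
    parental phenotypes are unknown.
    """
    records: List[PedigreeRecord] = []
    for k, t in enumerate(trios, start=1):
        fam = f"fam{k}"
        records.append(
            PedigreeRecord(fam, "father", "0", "0", 1, "unknown", (t.father_ms, None))
        )
        records.append(
            PedigreeRecord(fam, "mother", "0", "0", 2, "unknown", (t.mother_ms, None))
        )
        records.append(
            PedigreeRecord(
                fam,
                "child",
                "father",
                "mother",
                1,
                "affected",
                (t.child_ms, _SNP_ALLELES[t.child_snp]),
            )
        )
    return records, ["ms1", "snp1"]


def write_results_table(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a per-marker results TSV (tab-separated, header, 6-sig-fig floats)."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
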