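"""Readers and writers for the pipeline's file formats.

Formats handled here:

* molecule libraries as ``.smi`` (SMILES [whitespace] name) and CSV with
  configurable column names; optional SDF (V2000) import;
* Kd panels as CSV with compound rows and kinase columns, where a literal
  ``>N`` token (default ``>30000``) marks a censored, above-detection value;
* team submissions as YAML files following the challenge template
  (team, problem, ranked compound list with vendor info and rationale);
* custom SMARTS alert catalogs as plain text (one ``SMARTS<TAB>label`` per
  line).

Validation collects *all* schema violations in a file before reporting, so
a malformed submission is diagnosed in one pass.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from rdkit import Chem

from .chem import Molecule, SmilesParseError, canonical_key, parse_smiles
from .rubric import DEFAULT_CENSOR_BOUND_NM, KdPanel

__all__ = [
    "SubmissionEntry",
    "TeamSubmission",
    "SubmissionSet",
    "ValidationError",
    "read_molecules_smi",
    "write_molecules_smi",
    "read_molecules_csv",
    "read_molecules_sdf",
    "read_kd_table",
    "write_kd_table",
    "read_submission",
    "read_submissions",
    "write_submission",
    "read_smarts_catalog",
    "MAX_COMPOUNDS_PER_PROBLEM",
]

MAX_COMPOUNDS_PER_PROBLEM = 5


class ValidationError(ValueError):
    """One or more schema violations; ``errors`` lists every problem found."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class SubmissionEntry:
    rank: int
    name: str
    smiles: str
    vendor_name: str
    vendor_id: str
    rationale: str = ""


@dataclass(frozen=True)
class TeamSubmission:
    team: str
    problem: str
    entries: tuple[SubmissionEntry, ...]

    @property
    def top_ranked(self) -> SubmissionEntry:
        return min(self.entries, key=lambda e: e.rank)


@dataclass
class SubmissionSet:
    """All team submissions for one problem."""

    problem: str
    teams: list[TeamSubmission] = field(default_factory=list)

    def __iter__(self):
        return iter(self.teams)

    def __len__(self):
        return len(self.teams)


# ---------------------------------------------------------------- molecules


def read_molecules_smi(path) -> list[tuple[str, Molecule]]:
    """Read a .smi file: one ``SMILES [name]`` per line, '#' comments allowed."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
        try:
            out.append((name, parse_smiles(smiles)))
        except SmilesParseError as exc:
            raise SmilesParseError(f"{path} line {lineno}: {exc}") from exc
    return out


def write_molecules_smi(path, molecules: Iterable[tuple[str, str]]) -> None:
    """Write (name, smiles) pairs as a .smi file."""
    lines = [f"{smiles}\t{name}" for name, smiles in molecules]
    Path(path).write_text("\n".join(lines) + "\n")


def read_molecules_csv(
    path, smiles_column: str = "smiles", name_column: str = "name"
) -> list[tuple[str, Molecule]]:
    df = pd.read_csv(path)
    for col in (smiles_column, name_column):
        if col not in df.columns:
            raise ValidationError([f"{path}: missing column {col!r}"])
    out = []
    for _, row in df.iterrows():
        out.append((str(row[name_column]), parse_smiles(str(row[smiles_column]))))
    return out


def read_molecules_sdf(path) -> list[tuple[str, Molecule]]:
    """Read a V2000 SDF file; molecule name taken from the title line."""
    out = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, rd in enumerate(supplier):
        if rd is None:
            raise SmilesParseError(f"{path}: unparseable record #{i + 1}")
        name = rd.GetProp("_Name") if rd.HasProp("_Name") and rd.GetProp("_Name") else f"mol{i + 1}"
        smiles = Chem.MolToSmiles(rd)
        out.append((name, Molecule(rd, smiles)))
    return out


# ---------------------------------------------------------------- Kd panels


def read_kd_table(path, censor_token: str = ">30000") -> KdPanel:
    """Read a Kd CSV (compound rows, kinase columns, values in nM).

    Cells equal to ``censor_token`` (or any ``>N`` token) are censored at
    their stated bound; other cells must be positive numbers.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError([f"{path}: duplicate compound rows {dups}"])
    kd = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    cens = pd.DataFrame(False, index=df.index, columns=df.columns)
    errors = []
    for comp in df.index:
        for target in df.columns:
            raw = str(df.at[comp, target]).strip()
            if raw == censor_token or raw.startswith(">"):
                try:
                    bound = float(raw.lstrip(">"))
                except ValueError:
                    errors.append(f"row {comp!r}, column {target!r}: bad cell {raw!r}")
                    continue
                kd.at[comp, target] = bound
                cens.at[comp, target] = True
            else:
                try:
                    val = float(raw)
                except ValueError:
                    errors.append(f"row {comp!r}, column {target!r}: bad cell {raw!r}")
                    continue
                if val <= 0:
                    errors.append(f"row {comp!r}, column {target!r}: non-positive Kd {val}")
                    continue
                kd.at[comp, target] = val
    if errors:
        raise ValidationError([f"{path}: {e}" for e in errors])
    return KdPanel(kd, cens)


def write_kd_table(path, panel: KdPanel, censor_token_prefix: str = ">") -> None:
    """Write a Kd panel as CSV, censored cells as ``>bound`` tokens."""
    out = panel.kd_nM.copy().astype(object)
    for comp in panel.compounds:
        for target in panel.targets:
            kd, cens = panel.entry(comp, target)
            out.at[comp, target] = (
                f"{censor_token_prefix}{kd:g}" if cens else f"{kd:g}"
            )
    out.index.name = "compound"
    out.to_csv(path)


# -------------------------------------------------------------- submissions


def _validate_submission_dict(raw: dict, source: str) -> list[str]:
    errors = []
    for key in ("team", "problem", "compounds"):
        if key not in raw:
            errors.append(f"{source}: missing top-level field {key!r}")
    compounds = raw.get("compounds", [])
    if not isinstance(compounds, list):
        errors.append(f"{source}: 'compounds' must be a list")
        return errors
    if len(compounds) > MAX_COMPOUNDS_PER_PROBLEM:
        errors.append(
            f"{source}: {len(compounds)} compounds exceeds the template limit "
            f"of {MAX_COMPOUNDS_PER_PROBLEM}"
        )
    ranks = []
    for i, entry in enumerate(compounds, 1):
        where = f"{source} compound #{i}"
        for key in ("rank", "name", "smiles", "vendor"):
            if key not in entry:
                errors.append(f"{where}: missing field {key!r}")
        vendor = entry.get("vendor", {})
        if isinstance(vendor, dict):
            for key in ("name", "id"):
                if key not in vendor:
                    errors.append(f"{where}: missing vendor field {key!r}")
        else:
            errors.append(f"{where}: 'vendor' must be a mapping")
        if "rank" in entry:
            ranks.append(entry["rank"])
        if "smiles" in entry:
            try:
                parse_smiles(str(entry["smiles"]))
            except SmilesParseError as exc:
                errors.append(f"{where} (team {raw.get('team', '?')}): {exc}")
    if len(ranks) != len(set(ranks)):
        errors.append(f"{source}: duplicate ranks {sorted(ranks)}")
    return errors


def read_submission(path) -> TeamSubmission:
    """Read and validate one team-submission YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    errors = _validate_submission_dict(raw, str(path))
    if errors:
        raise ValidationError(errors)
    entries = tuple(
        SubmissionEntry(
            rank=int(e["rank"]),
            name=str(e["name"]),
            smiles=str(e["smiles"]),
            vendor_name=str(e["vendor"]["name"]),
            vendor_id=str(e["vendor"]["id"]),
            rationale=str(e.get("rationale", "")),
        )
        for e in sorted(raw["compounds"], key=lambda e: e["rank"])
    )
    return TeamSubmission(team=str(raw["team"]), problem=str(raw["problem"]), entries=entries)


def read_submissions(paths: Sequence, problem: str | None = None) -> SubmissionSet:
    """Read several submission files into one :class:`SubmissionSet`.

    All files' validation errors are pooled and reported together.
    """
    teams, errors = [], []
    for path in paths:
        try:
            teams.append(read_submission(path))
        except ValidationError as exc:
            errors.extend(exc.errors)
    if errors:
        raise ValidationError(errors)
    problems = {t.problem for t in teams}
    if problem is None:
        if len(problems) > 1:
            raise ValidationError([f"mixed problems in submission set: {sorted(problems)}"])
        problem = next(iter(problems)) if problems else ""
    return SubmissionSet(problem=problem, teams=teams)


def write_submission(path, sub: TeamSubmission) -> None:
    raw = {
        "team": sub.team,
        "problem": sub.problem,
        "compounds": [
            {
                "rank": e.rank,
                "name": e.name,
                "smiles": e.smiles,
                "vendor": {"name": e.vendor_name, "id": e.vendor_id},
                "rationale": e.rationale,
            }
            for e in sub.entries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ------------------------------------------------------------ alert catalogs


def read_smarts_catalog(path) -> list[tuple[str, str]]:
    """Read a plain-text SMARTS catalog: one ``SMARTS<TAB>label`` per line."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(None, 1)
        if len(parts) != 2:
            raise ValidationError([f"{path} line {lineno}: expected 'SMARTS label'"])
        out.append((parts[0], parts[1]))
    return out
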