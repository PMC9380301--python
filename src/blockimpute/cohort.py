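"""Domain types and file I/O for block-structured clinical data matrices.

A clinical cohort is an ``n`` participants by ``p`` variables matrix ``D``
with three cell states:

* observed — a finite value;
* missing — intended to be acquired but absent (the imputation target);
* structurally absent — never intended for that participant's group
  (e.g. an autism diagnostic interview in a typically-developing control);
  these cells are never imputed.

Variables are typed (continuous / ordinal / nominal); discrete variables
carry an ordered level set. The cohort's planned-missingness layout is a
:class:`SubsetDesign`: a partition of the imputable variables into blocks,
each acquired for a declared participant set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ContainmentError,
    DesignError,
    FormatError,
    ValidationError,
)

VARIABLE_KINDS = ("continuous", "ordinal", "nominal")

DEFAULT_SENTINELS = ("", "NA", "NaN", "nan")


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one variable: its name, kind, and (for discrete
    variables) the ordered set of admissible levels."""

    name: str
    kind: str
    levels: tuple[float, ...] = ()
    imputable: bool = True

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise ValidationError(
                f"variable {self.name!r}: unknown kind {self.kind!r}"
            )
        if self.kind == "continuous":
            if self.levels:
                raise ValidationError(
                    f"continuous variable {self.name!r} must not declare levels"
                )
        else:
            if len(self.levels) < 2:
                raise ValidationError(
                    f"{self.kind} variable {self.name!r} needs >= 2 levels"
                )
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))

    @property
    def is_discrete(self) -> bool:
        return self.kind in ("ordinal", "nominal")


class ClinicalMatrix:
    """The data matrix ``D`` with its missingness mask and variable metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Float frame indexed by participant id, columns = variable names.
        ``NaN`` marks a cell with no value (missing or structurally absent).
    specs : sequence of VariableSpec
        One spec per column, same order as ``values.columns``.
    structural : pandas.DataFrame of bool, optional
        True where a cell is structurally absent (never acquired by design).
        Structural cells must be NaN in ``values``.
    """

    def __init__(self, values: pd.DataFrame, specs, structural=None):
        values = values.astype(float)
        specs = list(specs)
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate variable names in specs")
        if list(values.columns) != names:
            raise ValidationError("specs do not match matrix columns")
        if values.index.has_duplicates:
            raise ValidationError("duplicate participant ids")
        values.index.name = None
        if structural is None:
            structural = pd.DataFrame(
                False, index=values.index, columns=values.columns
            )
        else:
            structural = structural.reindex(
                index=values.index, columns=values.columns
            ).fillna(False).astype(bool)
            if (structural.to_numpy() & values.notna().to_numpy()).any():
                raise ValidationError("structurally absent cells must be empty")
        self.values = values
        self.specs = specs
        self.structural = structural
        self._spec_by_name = {s.name: s for s in specs}
        self._check_levels()

    def _check_levels(self) -> None:
        for spec in self.specs:
            if not spec.is_discrete:
                continue
            col = self.values[spec.name].dropna()
            bad = ~col.isin(spec.levels)
            if bad.any():
                offender = col[bad].iloc[0]
                raise ValidationError(
                    f"observed value {offender!r} of {spec.kind} variable "
                    f"{spec.name!r} outside declared levels {spec.levels}"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def participant_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """True where a cell is missing (absent but not structural)."""
        return self.values.isna() & ~self.structural

    @property
    def m(self) -> int:
        """Total missing count, m = sum_j m_j."""
        return int(self.missing_mask.to_numpy().sum())

    @property
    def m_j(self) -> pd.Series:
        """Missing count per variable."""
        return self.missing_mask.sum(axis=0)

    def observed_index(self, variable: str) -> pd.Index:
        """O_j: participant ids with an observed value at ``variable``."""
        return self.values.index[self.values[variable].notna()]

    def spec(self, variable: str) -> VariableSpec:
        try:
            return self._spec_by_name[variable]
        except KeyError:
            raise ValidationError(f"unknown variable {variable!r}") from None

    def copy(self) -> "ClinicalMatrix":
        return ClinicalMatrix(
            self.values.copy(), list(self.specs), self.structural.copy()
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ClinicalMatrix(n={self.n}, p={self.p}, m={self.m}, "
            f"structural={int(self.structural.to_numpy().sum())})"
        )


@dataclass(frozen=True)
class Subset:
    """One block of the planned-missingness design."""

    subset_id: int
    participants: frozenset
    variables: tuple[str, ...]
    group_label: str = ""


@dataclass
class SubsetDesign:
    """The block layout: which participants x which variables each subset
    spans, plus per-participant group labels (diagnosis, schedule)."""

    subsets: list[Subset]
    groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subset_id for s in self.subsets]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate subset ids")

    def subset(self, subset_id: int) -> Subset:
        for s in self.subsets:
            if s.subset_id == subset_id:
                return s
        raise DesignError(f"unknown subset id {subset_id}")

    def subset_of_variable(self, variable: str) -> Subset:
        for s in self.subsets:
            if variable in s.variables:
                return s
        raise DesignError(f"variable {variable!r} belongs to no subset")

    def validate(self, matrix: ClinicalMatrix) -> None:
        """Check consistency against a matrix: variables exist, participants
        exist, and imputable variables are partitioned across subsets."""
        seen: dict[str, int] = {}
        participants = set(matrix.participant_ids)
        for s in self.subsets:
            for v in s.variables:
                if v not in matrix._spec_by_name:
                    raise DesignError(
                        f"subset {s.subset_id} references unknown variable {v!r}"
                    )
                if v in seen:
                    raise DesignError(
                        f"variable {v!r} appears in subsets {seen[v]} "
                        f"and {s.subset_id}"
                    )
                seen[v] = s.subset_id
            unknown = set(s.participants) - participants
            if unknown:
                raise DesignError(
                    f"subset {s.subset_id} references unknown participants "
                    f"{sorted(unknown)[:3]}"
                )
        uncovered = [
            sp.name
            for sp in matrix.specs
            if sp.imputable and sp.name not in seen
        ]
        if uncovered:
            raise DesignError(
                f"imputable variables belong to no subset: {uncovered[:5]}"
            )


@dataclass
class MissingnessSummary:
    """Per-subset and overall missingness accounting (Table-1 style)."""

    per_subset: pd.DataFrame  # subset_id, n, p, missing, percent_missing
    per_variable: pd.Series  # m_j
    total_missing: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def summarize_missingness(
    matrix: ClinicalMatrix, design: SubsetDesign
) -> MissingnessSummary:
    """One row per subset with (n, p, % missing), plus totals.

    The percentage is over the subset's own block: missing cells divided by
    block n*p, times 100.
    """
    design.validate(matrix)
    mask = matrix.missing_mask
    rows = []
    for s in design.subsets:
        pids = [p for p in matrix.participant_ids if p in s.participants]
        block = mask.loc[pids, list(s.variables)]
        n_b, p_b = block.shape
        miss = int(block.to_numpy().sum())
        pct = 100.0 * miss / (n_b * p_b) if n_b * p_b else 0.0
        rows.append(
            {
                "subset_id": s.subset_id,
                "n": n_b,
                "p": p_b,
                "missing": miss,
                "percent_missing": pct,
            }
        )
    per_subset = pd.DataFrame(rows).set_index("subset_id")
    return MissingnessSummary(
        per_subset=per_subset,
        per_variable=matrix.m_j,
        total_missing=matrix.m,
    )


def subset_view(
    matrix: ClinicalMatrix,
    design: SubsetDesign,
    subset_id: int,
    extra_variables=(),
) -> ClinicalMatrix:
    """Restrict the matrix to a subset's participants and variables, plus
    conditioning columns from other subsets.

    Every extra variable's owning subset must cover the target subset's
    participants (the cascade's admissibility rule); otherwise a
    :class:`ContainmentError` is raised. Row index and column names are
    preserved so imputed values can be written back by label.
    """
    target = design.subset(subset_id)
    extra_variables = [v for v in extra_variables if v not in target.variables]
    for v in extra_variables:
        owner = design.subset_of_variable(v)
        if not target.participants <= owner.participants:
            raise ContainmentError(
                f"conditioning variable {v!r} (subset {owner.subset_id}) does "
                f"not cover all participants of subset {subset_id}"
            )
    pids = [p for p in matrix.participant_ids if p in target.participants]
    cols = list(target.variables) + list(extra_variables)
    values = matrix.values.loc[pids, cols].copy()
    structural = matrix.structural.loc[pids, cols].copy()
    specs = [matrix.spec(c) for c in cols]
    return ClinicalMatrix(values, specs, structural)


def write_back(
    matrix: ClinicalMatrix,
    design: SubsetDesign,
    subset_id: int,
    completed: pd.DataFrame,
) -> None:
    """Write imputed values from a subset view back into ``matrix``,
    touching only the target subset's originally missing cells."""
    target = design.subset(subset_id)
    pids = [p for p in matrix.participant_ids if p in target.participants]
    for v in target.variables:
        col_mask = matrix.missing_mask.loc[pids, v]
        fill_rows = col_mask.index[col_mask]
        matrix.values.loc[fill_rows, v] = completed.loc[fill_rows, v]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _parse_cell(raw, sentinels) -> float:
    if raw is None:
        return np.nan
    text = str(raw).strip()
    if text in sentinels:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"unparseable cell value {raw!r}") from None


def load_metadata(path) -> list[VariableSpec]:
    """Read variable metadata from CSV (name, kind, levels, imputable) or a
    JSON list of objects with the same fields. Levels are semicolon-joined
    in CSV."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            records = json.load(fh)
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        records = frame.to_dict("records")
    specs = []
    for rec in records:
        if "name" not in rec or "kind" not in rec:
            raise FormatError("metadata rows need 'name' and 'kind'")
        levels = rec.get("levels", "") or ""
        if isinstance(levels, str):
            levels = tuple(float(tok) for tok in levels.split(";") if tok != "")
        else:
            levels = tuple(float(v) for v in levels)
        imputable = rec.get("imputable", True)
        if isinstance(imputable, str):
            imputable = imputable.strip().lower() in ("1", "true", "yes")
        specs.append(
            VariableSpec(
                name=str(rec["name"]),
                kind=str(rec["kind"]),
                levels=levels,
                imputable=bool(imputable),
            )
        )
    return specs


def load_matrix(
    path,
    metadata_path,
    sentinels=DEFAULT_SENTINELS,
    structural_path=None,
) -> ClinicalMatrix:
    """Load a delimited data matrix plus its variable metadata.

    The table's header row holds variable names and the first column holds
    participant ids. Cells equal to any sentinel (empty string, "NA", ...)
    become missing. An optional structural-absence sidecar lists
    (participant, variable) pairs never acquired by design.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError("matrix file needs an id column plus variables")
    raw = raw.set_index(raw.columns[0])
    specs = load_metadata(metadata_path)
    names = [s.name for s in specs]
    if set(names) != set(raw.columns):
        missing = set(names) ^ set(raw.columns)
        raise FormatError(
            f"metadata and matrix header disagree on variables: {sorted(missing)[:5]}"
        )
    sentinels = set(sentinels)
    values = raw[names].map(lambda cell: _parse_cell(cell, sentinels))
    structural = None
    if structural_path is not None:
        pairs = pd.read_csv(structural_path, dtype=str)
        structural = pd.DataFrame(False, index=values.index, columns=values.columns)
        for _, row in pairs.iterrows():
            structural.loc[row.iloc[0], row.iloc[1]] = True
    return ClinicalMatrix(values, specs, structural)


def write_matrix(
    matrix: ClinicalMatrix,
    path,
    metadata_path=None,
    structural_path=None,
) -> None:
    """Write a matrix (missing cells as empty fields) and optionally its
    metadata table and structural-absence sidecar."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    out = matrix.values.copy()
    out.index.name = "participant_id"
    out.to_csv(path, sep=sep, na_rep="")
    if metadata_path is not None:
        rows = [
            {
                "name": s.name,
                "kind": s.kind,
                "levels": ";".join(format(v, "g") for v in s.levels),
                "imputable": s.imputable,
            }
            for s in matrix.specs
        ]
        pd.DataFrame(rows).to_csv(metadata_path, index=False)
    if structural_path is not None:
        pairs = [
            {"participant_id": pid, "variable": var}
            for var in matrix.variable_names
            for pid in matrix.structural.index[matrix.structural[var]]
        ]
        pd.DataFrame(
            pairs, columns=["participant_id", "variable"]
        ).to_csv(structural_path, index=False)


def load_design(path) -> SubsetDesign:
    """Read a subset design from JSON: {"groups": {pid: label}, "subsets":
    [{"id", "participants", "variables", "group_label"}]}."""
    with open(path) as fh:
        payload = json.load(fh)
    subsets = [
        Subset(
            subset_id=int(rec["id"]),
            participants=frozenset(rec["participants"]),
            variables=tuple(rec["variables"]),
            group_label=rec.get("group_label", ""),
        )
        for rec in payload["subsets"]
    ]
    return SubsetDesign(subsets=subsets, groups=payload.get("groups", {}))


def write_design(design: SubsetDesign, path) -> None:
    payload = {
        "groups": dict(design.groups),
        "subsets": [
            {
                "id": s.subset_id,
                "participants": sorted(s.participants),
                "variables": list(s.variables),
                "group_label": s.group_label,
            }
            for s in design.subsets
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
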