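"""Cohort container, variable-kind metadata, encoding rules and file I/O.

A cohort is one row per subject: follow-up time, event indicator, and typed
predictor columns.  Variable kinds drive split-candidate enumeration:

- ``binary``       one candidate (the single two-way partition)
- ``continuous``   midpoint thresholds (or quartile cuts)
- ``categorical``  one-vs-rest per level
- ``genotype012``  additive SNP coding 0/1/2; dominant and recessive partitions
- ``ordered3``     3-level ordered score (e.g. drug immunogenicity group)

Files are plain CSV/TSV with a JSON schema sidecar mapping columns to kinds;
PLINK-RAW-style additive genotype columns (0/1/2 with NA) load as
``genotype012``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VALID_KINDS",
    "Cohort",
    "load_cohort",
    "save_cohort",
    "impute_missing",
    "maf_filter",
    "encode_treatment",
    "DEFAULT_DRUG_GROUPS",
]

VALID_KINDS = ("binary", "continuous", "categorical", "genotype012", "ordered3")

# Drug -> immunogenicity group mapping used by the ABIRISK-style analysis:
# low (0), intermediate (1), high (2).
DEFAULT_DRUG_GROUPS = {
    "Etanercept": 0,
    "IFNb-1a im": 0,
    "Tocilizumab": 1,
    "Infliximab": 1,
    "IFNb-1a sc": 1,
    "Rituximab": 2,
    "Adalimumab": 2,
    "IFNb-1b sc": 2,
}


@dataclass
class Cohort:
    """Subjects x (time, event, typed predictors).

    ``data`` holds one column per variable (float-coded; categorical levels as
    integer codes); ``kinds`` maps every variable column to its kind.  Missing
    values are NaN; :func:`impute_missing` removes them before forest fitting.
    """

    time: np.ndarray
    event: np.ndarray
    data: pd.DataFrame
    kinds: dict[str, str]
    ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = self.time.size
        if self.event.size != n or len(self.data) != n:
            raise ValueError("time, event and data must have the same length")
        if np.any(self.time < 0) or np.any(np.isnan(self.time)):
            raise ValueError("follow-up times must be nonnegative")
        ev = np.unique(self.event)
        if not np.all(np.isin(ev, [0, 1])):
            raise ValueError(f"event indicator must be 0/1, got values {ev}")
        self.event = self.event.astype(np.int8)
        if self.ids is None:
            self.ids = np.arange(n)
        else:
            self.ids = np.asarray(self.ids)
        missing_meta = [c for c in self.data.columns if c not in self.kinds]
        if missing_meta:
            raise ValueError(f"variables without a kind: {missing_meta}")
        for name, kind in self.kinds.items():
            if kind not in VALID_KINDS:
                raise ValueError(f"unknown kind {kind!r} for column {name!r}")
            if kind == "genotype012":
                vals = self.data[name].dropna().unique()
                bad = [v for v in vals if v not in (0, 1, 2)]
                if bad:
                    raise ValueError(
                        f"genotype column {name!r} has non-0/1/2 values: {bad}")
        self.data = self.data.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    @property
    def variable_names(self) -> list[str]:
        return list(self.data.columns)

    def kinds_array(self) -> list[str]:
        return [self.kinds[c] for c in self.data.columns]

    def as_arrays(self):
        """(X, kinds, names) with X an ``n x m`` float matrix."""
        X = self.data.to_numpy(dtype=float)
        return X, self.kinds_array(), self.variable_names

    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def subset_variables(self, names) -> "Cohort":
        return Cohort(
            time=self.time.copy(), event=self.event.copy(),
            data=self.data[list(names)].copy(),
            kinds={c: self.kinds[c] for c in names},
            ids=self.ids.copy(),
        )

    def add_variables(self, frame: pd.DataFrame, kinds: dict[str, str]) -> "Cohort":
        merged = pd.concat([self.data.reset_index(drop=True),
                            frame.reset_index(drop=True)], axis=1)
        return Cohort(time=self.time.copy(), event=self.event.copy(),
                      data=merged, kinds={**self.kinds, **kinds},
                      ids=self.ids.copy())


def load_cohort(path, schema=None) -> Cohort:
    """Read a delimited cohort file with its schema.

    ``schema`` is a dict (or path to a JSON file) with keys ``time``, ``event``,
    optionally ``id``, and ``kinds`` mapping variable columns to kinds.  When
    omitted, ``<path>.schema.json`` is read.
    """
    path = Path(path)
    if schema is None:
        schema = path.with_suffix(path.suffix + ".schema.json")
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = json.load(fh)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    for key in ("time", "event"):
        if schema.get(key) not in df.columns:
            raise ValueError(f"schema {key} column {schema.get(key)!r} not in file")
    time = df[schema["time"]].to_numpy(dtype=float)
    event_raw = df[schema["event"]].to_numpy()
    bad_ev = np.setdiff1d(np.unique(event_raw), [0, 1])
    if bad_ev.size:
        raise ValueError(f"event column has values outside 0/1: {bad_ev}")
    ids = df[schema["id"]].to_numpy() if schema.get("id") in df.columns else None
    kinds = dict(schema["kinds"])
    drop = [schema["time"], schema["event"]] + ([schema["id"]] if schema.get("id") in df.columns else [])
    variables = df.drop(columns=drop)
    variables = variables[[c for c in variables.columns if c in kinds]]
    return Cohort(time=time, event=event_raw, data=variables, kinds=kinds, ids=ids)


def save_cohort(cohort: Cohort, path, id_col="subject_id",
                time_col="time", event_col="event") -> None:
    """Write CSV/TSV plus the JSON schema sidecar (round-trips with load)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    out = pd.DataFrame({id_col: cohort.ids, time_col: cohort.time,
                        event_col: cohort.event})
    out = pd.concat([out, cohort.data.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=sep, index=False)
    schema = {"time": time_col, "event": event_col, "id": id_col,
              "kinds": cohort.kinds}
    with open(path.with_suffix(path.suffix + ".schema.json"), "w") as fh:
        json.dump(schema, fh, indent=1)


def impute_missing(cohort: Cohort):
    """Mean (continuous) / most-common-class (all other kinds) imputation.

    Ties on the modal class resolve to the lowest value.  Returns the imputed
    cohort and a report ``{column: n_imputed}``.
    """
    report: dict[str, int] = {}
    if not cohort.has_missing():
        return cohort, report
    data = cohort.data.copy()
    for name in data.columns:
        col = data[name]
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            continue
        observed = col.dropna()
        if observed.empty:
            raise ValueError(f"column {name!r} is entirely missing")
        if cohort.kinds[name] == "continuous":
            fill = float(observed.mean())
        else:
            counts = observed.value_counts()
            top = counts[counts == counts.max()]
            fill = float(min(top.index))
        data[name] = col.fillna(fill)
        report[name] = n_missing
    return Cohort(time=cohort.time.copy(), event=cohort.event.copy(),
                  data=data, kinds=dict(cohort.kinds), ids=cohort.ids.copy()), report


def maf_filter(cohort: Cohort, threshold: float = 0.25):
    """Drop genotype columns with folded minor allele frequency <= threshold.

    Allele frequency is the alternative-allele count ``(n1 + 2 n2) / (2 n)``
    over non-missing genotypes, folded to ``<= 0.5``.  Returns the filtered
    cohort and the list of dropped column names.
    """
    dropped = []
    keep = []
    for name in cohort.data.columns:
        if cohort.kinds[name] != "genotype012":
            keep.append(name)
            continue
        g = cohort.data[name].dropna().to_numpy()
        if g.size == 0:
            dropped.append(name)
            continue
        freq = (np.sum(g == 1) + 2 * np.sum(g == 2)) / (2 * g.size)
        maf = min(freq, 1.0 - freq)
        (keep if maf > threshold else dropped).append(name)
    return cohort.subset_variables(keep), dropped


def encode_treatment(labels, drug_groups: dict[str, int] | None = None):
    """Encode drug labels as the ordered immunogenicity score plus dummies.

    Returns ``(frame, kinds)``: one ``ordered3`` column (0=low, 1=intermediate,
    2=high immunogenicity group) and one 0/1 dummy column per distinct drug
    (one drug vs. the others).
    """
    groups = DEFAULT_DRUG_GROUPS if drug_groups is None else drug_groups
    labels = pd.Series(labels).astype(str)
    unknown = sorted(set(labels) - set(groups))
    if unknown:
        raise ValueError(f"drugs without an immunogenicity group: {unknown}")
    frame = pd.DataFrame({"immunogenicity_group": labels.map(groups).astype(float)})
    kinds = {"immunogenicity_group": "ordered3"}
    for drug in sorted(labels.unique()):
        col = f"drug_{drug.replace(' ', '_')}"
        frame[col] = (labels == drug).astype(float)
        kinds[col] = "binary"
    return frame, kinds
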