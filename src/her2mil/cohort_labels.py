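"""HER2 group derivation, model-specific case partitions, and patient-level splits.

HER2 status is scored by immunohistochemistry (IHC: 0, 1+, 2+, 3+); equivocal
2+ cases are resolved by an in-situ hybridization assay (ISH: amplified or not).
The three clinical groups are

* ``neg``  — IHC 0
* ``low``  — IHC 1+, or IHC 2+ with a negative ISH result
* ``high`` — IHC 2+ with a positive ISH result, or IHC 3+

Six training partitions (M1–M6) select different subsets of the five
assay-result cells and map them onto two or three classes, so that each model
probes a different clinical contrast (e.g. M1: resolve the equivocal 2+ group
without an ISH test; M5: separate neg from low, the contrast most affected by
0 vs 1+ interobserver disagreement).

Splitting is patient-level and stratified on (partition label, cohort): a
hold-out test fraction is removed once, then each cross-validation fold
independently re-draws a validation fraction from the remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

IHC_SCORES = ("0", "1+", "2+", "3+")
ISH_STATUSES = ("neg", "pos", "absent")
HER2_GROUPS = ("neg", "low", "high")

#: The five legal (ihc, ish) assay-result cells.
ASSAY_CELLS = (
    ("0", "absent"),
    ("1+", "absent"),
    ("2+", "neg"),
    ("2+", "pos"),
    ("3+", "absent"),
)

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5", "M6")


class EquivocalCaseError(ValueError):
    """IHC 2+ without a confirmatory ISH result cannot be assigned a group."""


def _canonical_ihc(ihc) -> str:
    s = str(ihc).strip()
    if s in ("0", "1", "2", "3"):
        return s if s == "0" else s + "+"
    if s in IHC_SCORES:
        return s
    raise ValueError(f"unknown IHC score: {ihc!r}")


def _canonical_ish(ish) -> str:
    s = str(ish).strip().lower()
    if s in ("", "na", "nan", "none", "absent"):
        return "absent"
    if s in ("neg", "negative"):
        return "neg"
    if s in ("pos", "positive"):
        return "pos"
    raise ValueError(f"unknown ISH status: {ish!r}")


def assign_her2_group(ihc, ish="absent") -> str:
    """Map an (IHC score, ISH status) pair to its HER2 group.

    Raises
    ------
    EquivocalCaseError
        For IHC 2+ without an ISH result (equivocal by definition).
    """
    ihc = _canonical_ihc(ihc)
    ish = _canonical_ish(ish)
    if ihc == "2+":
        if ish == "absent":
            raise EquivocalCaseError("IHC 2+ requires an ISH result")
        return "low" if ish == "neg" else "high"
    if ihc == "0":
        return "neg"
    if ihc == "1+":
        return "low"
    return "high"  # 3+


@dataclass(frozen=True)
class SlideRecord:
    """One slide with its assay results and derived HER2 group."""

    slide_id: str
    patient_id: str
    cohort: str
    ihc: str
    ish: str = "absent"
    her2_group: str = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "ihc", _canonical_ihc(self.ihc))
        object.__setattr__(self, "ish", _canonical_ish(self.ish))
        object.__setattr__(self, "her2_group", assign_her2_group(self.ihc, self.ish))


@dataclass(frozen=True)
class PartitionSpec:
    """A training partition: which assay cells are included and how they map to classes."""

    model_id: str
    class_map: dict  # (ihc, ish) cell -> group label

    @property
    def included_cells(self) -> frozenset:
        return frozenset(self.class_map)

    @property
    def classes(self) -> tuple:
        """Distinct mapped classes in fixed neg < low < high order."""
        present = set(self.class_map.values())
        return tuple(g for g in HER2_GROUPS if g in present)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_index(self, group: str) -> int:
        return self.classes.index(group)


def _spec(model_id, cells):
    return PartitionSpec(model_id, dict(cells))


#: Cell-to-class maps of the six models. Excluded cells are dropped, never relabeled.
PARTITIONS: dict = {
    "M1": _spec("M1", {("2+", "neg"): "low", ("2+", "pos"): "high", ("3+", "absent"): "high"}),
    "M2": _spec("M2", {("0", "absent"): "neg", ("2+", "pos"): "high", ("3+", "absent"): "high"}),
    "M3": _spec(
        "M3",
        {
            ("1+", "absent"): "low",
            ("2+", "neg"): "low",
            ("2+", "pos"): "high",
            ("3+", "absent"): "high",
        },
    ),
    # M4 default: 3-class, excludes the ISH-amplified 2+ cell (override via build_partition).
    "M4": _spec(
        "M4",
        {
            ("0", "absent"): "neg",
            ("1+", "absent"): "low",
            ("2+", "neg"): "low",
            ("3+", "absent"): "high",
        },
    ),
    "M5": _spec("M5", {("0", "absent"): "neg", ("1+", "absent"): "low", ("2+", "neg"): "low"}),
    "M6": _spec("M6", {cell: assign_her2_group(*cell) for cell in ASSAY_CELLS}),
}


def build_partition(model_id, records, class_map=None):
    """Select the slides a model trains on and attach their partition labels.

    Parameters
    ----------
    model_id : str
        One of M1..M6.
    records : pandas.DataFrame
        Slide manifest with columns ``slide_id, patient_id, cohort, ihc, ish``.
    class_map : dict, optional
        Override of the model's cell-to-class map (used for the M4 variants).

    Returns
    -------
    (pandas.DataFrame, PartitionSpec)
        The retained records with a ``label`` column, and the partition spec.
    """
    if model_id not in PARTITIONS:
        raise ValueError(f"unknown model id: {model_id!r}")
    spec = PARTITIONS[model_id] if class_map is None else _spec(model_id, class_map)
    df = records.copy()
    df["ihc"] = df["ihc"].map(_canonical_ihc)
    df["ish"] = df["ish"].map(_canonical_ish)
    cells = list(zip(df["ihc"], df["ish"]))
    keep = [c in spec.class_map for c in cells]
    out = df.loc[keep].copy()
    out["label"] = [spec.class_map[c] for c, k in zip(cells, keep) if k]
    return out.reset_index(drop=True), spec


def manifest_from_records(records) -> pd.DataFrame:
    """Build a manifest DataFrame from SlideRecord objects."""
    return pd.DataFrame(
        {
            "slide_id": [r.slide_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "cohort": [r.cohort for r in records],
            "ihc": [r.ihc for r in records],
            "ish": [r.ish for r in records],
            "her2_group": [r.her2_group for r in records],
        }
    )


def read_manifest(path) -> pd.DataFrame:
    """Read a slide manifest CSV (columns slide_id,patient_id,cohort,ihc,ish)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["ihc"] = df["ihc"].map(_canonical_ihc)
    df["ish"] = df["ish"].map(_canonical_ish)
    df["her2_group"] = [assign_her2_group(i, s) for i, s in zip(df["ihc"], df["ish"])]
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["ihc"] = out["ihc"].str.rstrip("+")
    out["ish"] = out["ish"].replace({"absent": "NA"})
    out[["slide_id", "patient_id", "cohort", "ihc", "ish"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    holdout_fraction: float = 0.15
    n_folds: int = 10
    val_fraction: float = 0.15
    seed: int = 0
    external_cohorts: tuple = ()  # cohorts held back as external test only


@dataclass
class SplitAssignment:
    """Patient-level split: hold-out set plus per-fold train/validation draws."""

    holdout: list  # slide ids
    folds: list  # list of (train_slide_ids, val_slide_ids)
    external: list  # slide ids from external cohorts
    seed: int

    def to_frame(self, model_id="") -> pd.DataFrame:
        rows = [(s, "holdout", model_id) for s in self.holdout]
        rows += [(s, "external", model_id) for s in self.external]
        for k, (tr, va) in enumerate(self.folds):
            rows += [(s, f"fold_{k}_train", model_id) for s in tr]
            rows += [(s, f"fold_{k}_val", model_id) for s in va]
        return pd.DataFrame(rows, columns=["slide_id", "role", "model_id"])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_splits(records: pd.DataFrame, plan: SplitPlan, label_col="label") -> SplitAssignment:
    """Draw the hold-out set and the per-fold train/validation assignments.

    Stratified on (label, cohort) at the patient level: all slides of a patient
    share one role. Each fold independently re-draws its validation set from
    the non-hold-out patients, mirroring repeated stratified 85/15 splits
    rather than a disjoint k-fold partition. Deterministic under ``plan.seed``.
    """
    df = records.copy()
    external_mask = df["cohort"].isin(plan.external_cohorts)
    external_slides = df.loc[external_mask, "slide_id"].tolist()
    df = df.loc[~external_mask]

    # one row per patient; label/cohort taken from the patient's first slide
    patients = df.groupby("patient_id", sort=True).first().reset_index()
    strata = {}
    for _, row in patients.iterrows():
        strata.setdefault((row[label_col], row["cohort"]), []).append(row["patient_id"])

    # merge undersized strata into the nearest stratum sharing the label
    merged = True
    while merged:
        merged = False
        for key, pids in list(strata.items()):
            if len(pids) < 2 and len(strata) > 1:
                same_label = [k for k in strata if k != key and k[0] == key[0]]
                target = same_label[0] if same_label else next(k for k in strata if k != key)
                warnings.warn(
                    f"stratum {key} has {len(pids)} patient(s); merging into {target}",
                    stacklevel=2,
                )
                strata[target] = sorted(strata[target] + pids)
                del strata[key]
                merged = True
                break

    rng = np.random.default_rng(plan.seed)
    keys = sorted(strata)
    n_total = sum(len(strata[k]) for k in keys)
    target_total = _round_half_up(plan.holdout_fraction * n_total)

    holdout_pids, remaining = [], {}
    counts = {k: _round_half_up(plan.holdout_fraction * len(strata[k])) for k in keys}
    # remainder absorbed by the largest stratum
    largest = max(keys, key=lambda k: len(strata[k]))
    counts[largest] += target_total - sum(counts.values())
    counts[largest] = int(np.clip(counts[largest], 0, len(strata[largest])))
    for k in keys:
        pids = sorted(strata[k])
        sel = rng.choice(len(pids), size=counts[k], replace=False)
        chosen = {pids[i] for i in sel}
        holdout_pids += sorted(chosen)
        remaining[k] = [p for p in pids if p not in chosen]

    folds = []
    slide_of = df.groupby("patient_id")["slide_id"].apply(list).to_dict()

    def slides(pids):
        return [s for p in sorted(pids) for s in slide_of[p]]

    for _ in range(plan.n_folds):
        train_p, val_p = [], []
        for k in keys:
            pids = remaining[k]
            if not pids:
                continue
            n_val = _round_half_up(plan.val_fraction * len(pids))
            n_val = min(max(n_val, 1 if len(pids) > 1 else 0), len(pids) - 1)
            sel = rng.choice(len(pids), size=n_val, replace=False)
            chosen = {pids[i] for i in sel}
            val_p += sorted(chosen)
            train_p += [p for p in pids if p not in chosen]
        folds.append((slides(train_p), slides(val_p)))

    return SplitAssignment(
        holdout=slides(holdout_pids), folds=folds, external=external_slides, seed=plan.seed
    )
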