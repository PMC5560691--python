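"""Reading, validating and writing Cq tables.

A qPCR run reports, for every (sample, target) well, a quantification cycle
(Cq).  Wells that never cross the fluorescence threshold before the
instrument's maximum cycle -- the limit of detection (LOD) -- are exported as
"Undetermined".  Statistically such a well is *right censored*: all we know is
that the latent Cq is at least the LOD.  This module encodes that convention:
an undetermined well, or any well with an observed Cq at or above the LOD, is
stored as a censored observation with its Cq set equal to the LOD
(``C = min(C*, LOD)``).

Wells that are absent for technical reasons unrelated to expression level
(e.g. a failed pipetting step) can be marked with an explicit *missing* token;
they are excluded from all analyses rather than treated as censored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CqDataset",
    "CqValidationError",
    "CqParseError",
    "DEFAULT_UNDETERMINED_TOKENS",
    "DEFAULT_MISSING_TOKENS",
    "read_cq_table",
    "write_cq_table",
    "write_results",
    "read_results",
    "make_dataset",
]

DEFAULT_UNDETERMINED_TOKENS = frozenset({"Undetermined", "undetermined", "NA", ""})
DEFAULT_MISSING_TOKENS = frozenset({"missing", "Missing"})


class CqValidationError(ValueError):
    """A structurally invalid Cq dataset (duplicates, bad groups, bad LOD...)."""


class CqParseError(ValueError):
    """A raw Cq cell that is neither numeric nor a recognized token."""


@dataclass
class CqDataset:
    """Long-form collection of Cq observations plus annotations.

    Attributes
    ----------
    data
        One row per observed well with columns ``sample_id``, ``target_id``,
        ``group``, ``cq``, ``censored``.  Censored rows carry ``cq == lod``.
        Missing (absent) wells are simply not present.
    lod
        Limit of detection in cycles; every uncensored ``cq`` is ``< lod``.
    samples
        Ordered sample annotation, indexed by sample_id, with a ``group``
        column.
    targets
        Ordered target annotation, indexed by target_id, with an
        ``is_reference`` column (1 for reference genes, 0 for targets of
        interest).
    """

    data: pd.DataFrame
    lod: float
    samples: pd.DataFrame
    targets: pd.DataFrame

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.samples.index)

    @property
    def target_ids(self) -> list:
        return list(self.targets.index)

    @property
    def groups(self) -> list:
        seen: dict = {}
        for g in self.samples["group"]:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return len(self.data)

    # -- matrix views ----------------------------------------------------
    def cq_matrix(self) -> pd.DataFrame:
        """Targets x samples matrix of stored Cq values (censored cells hold
        the LOD; absent wells are NaN)."""
        mat = self.data.pivot(index="target_id", columns="sample_id", values="cq")
        return mat.reindex(index=self.target_ids, columns=self.sample_ids)

    def censored_matrix(self) -> pd.DataFrame:
        """Targets x samples boolean matrix; absent wells are False."""
        mat = self.data.pivot(index="target_id", columns="sample_id", values="censored")
        mat = mat.reindex(index=self.target_ids, columns=self.sample_ids)
        return mat.fillna(False).astype(bool)

    # -- summaries -------------------------------------------------------
    def censored_fraction(self) -> float:
        if len(self.data) == 0:
            return 0.0
        return float(self.data["censored"].mean())

    def censoring_by_target(self) -> pd.DataFrame:
        """Per-target censored counts, overall and per group."""
        d = self.data.merge(
            self.samples["group"].rename("grp"), left_on="sample_id", right_index=True
        )
        rows = []
        for tid, sub in d.groupby("target_id", sort=False):
            row = {"target_id": tid, "n_obs": len(sub), "n_censored": int(sub["censored"].sum())}
            for g in self.groups:
                gsub = sub[sub["grp"] == g]
                row[f"n_censored[{g}]"] = int(gsub["censored"].sum())
                row[f"n_obs[{g}]"] = len(gsub)
            row["fraction"] = row["n_censored"] / row["n_obs"] if row["n_obs"] else 0.0
            rows.append(row)
        return pd.DataFrame(rows).set_index("target_id").reindex(self.target_ids)

    # -- transforms ------------------------------------------------------
    def with_lod(self, lod: float) -> "CqDataset":
        """Re-censor at a new LOD.  Lowering the LOD censors every stored Cq
        at or above it; raising it never un-censors (the latent value of a
        censored well is unknown)."""
        if lod <= 0:
            raise CqValidationError("lod must be positive")
        data = self.data.copy()
        hit = data["cq"] >= lod
        data.loc[hit, "censored"] = True
        data.loc[data["censored"], "cq"] = np.minimum(
            data.loc[data["censored"], "cq"], lod
        )
        return CqDataset(data, float(lod), self.samples.copy(), self.targets.copy())

    def subset_targets(self, target_ids) -> "CqDataset":
        keep = set(target_ids)
        data = self.data[self.data["target_id"].isin(keep)].reset_index(drop=True)
        targets = self.targets.loc[[t for t in self.target_ids if t in keep]]
        return CqDataset(data, self.lod, self.samples.copy(), targets)


def make_dataset(
    obs: pd.DataFrame,
    lod: float,
    samples: pd.DataFrame | None = None,
    targets: pd.DataFrame | None = None,
) -> CqDataset:
    """Assemble and validate a :class:`CqDataset` from a long observation
    frame with columns ``sample_id``, ``target_id``, ``cq``, ``censored``
    and optionally ``group``.
    """
    obs = obs.copy()
    required = {"sample_id", "target_id", "cq", "censored"}
    if not required.issubset(obs.columns):
        raise CqValidationError(f"observation frame needs columns {sorted(required)}")

    if samples is None:
        if "group" not in obs.columns:
            raise CqValidationError("group column or samples annotation required")
        samples = (
            obs[["sample_id", "group"]].drop_duplicates("sample_id").set_index("sample_id")
        )
    samples = samples.copy()
    if "group" not in samples.columns:
        raise CqValidationError("samples annotation needs a 'group' column")

    if targets is None:
        tids = obs["target_id"].drop_duplicates()
        targets = pd.DataFrame({"is_reference": 0}, index=pd.Index(tids, name="target_id"))
    targets = targets.copy()
    if "is_reference" not in targets.columns:
        targets["is_reference"] = 0
    targets["is_reference"] = targets["is_reference"].astype(int)

    # structural validation
    dup = obs.duplicated(subset=["sample_id", "target_id"])
    if dup.any():
        pair = obs.loc[dup.idxmax(), ["sample_id", "target_id"]]
        raise CqValidationError(
            f"duplicate observation for sample '{pair['sample_id']}' "
            f"and target '{pair['target_id']}'"
        )
    unknown_samples = set(obs["sample_id"]) - set(samples.index)
    if unknown_samples:
        raise CqValidationError(f"samples without group annotation: {sorted(map(str, unknown_samples))}")
    unknown_targets = set(obs["target_id"]) - set(targets.index)
    if unknown_targets:
        raise CqValidationError(f"targets without annotation: {sorted(map(str, unknown_targets))}")
    if samples["group"].isna().any():
        raise CqValidationError("unknown (NA) group label in sample annotation")
    if lod <= 0:
        raise CqValidationError("lod must be positive")

    obs["censored"] = obs["censored"].astype(bool)
    obs["cq"] = obs["cq"].astype(float)
    bad = (~obs["censored"]) & ~((obs["cq"] > 0) & (obs["cq"] < lod))
    if bad.any():
        raise CqValidationError(
            "uncensored cq values must satisfy 0 < cq < lod; offending rows: "
            f"{obs.index[bad].tolist()[:5]}"
        )
    obs.loc[obs["censored"], "cq"] = np.minimum(obs.loc[obs["censored"], "cq"], lod)

    if "group" in obs.columns:
        obs = obs.drop(columns=["group"])
    obs = obs.merge(samples["group"], left_on="sample_id", right_index=True)
    obs = obs[["sample_id", "target_id", "group", "cq", "censored"]].reset_index(drop=True)
    return CqDataset(obs, float(lod), samples, targets)


def _parse_cq_cell(value, lod, undetermined_tokens, missing_tokens, where: str):
    """Return (cq, censored, missing) for a raw cell."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        token = ""
    else:
        token = str(value).strip()
    if token in missing_tokens:
        return np.nan, False, True
    if token in undetermined_tokens:
        return float(lod), True, False
    try:
        cq = float(token)
    except ValueError:
        raise CqParseError(f"non-numeric cq value {value!r} at {where}") from None
    if cq >= lod:
        return float(lod), True, False
    return cq, False, False


def _read_table(path_or_buf, sep=None) -> pd.DataFrame:
    # comma/tab autodetection; keep everything as strings so that sentinel
    # tokens survive untouched
    return pd.read_csv(path_or_buf, sep=sep, engine="python", dtype=str,
                       keep_default_na=False)


def read_cq_table(
    path,
    format: str = "long",
    lod: float = 40.0,
    undetermined_tokens=DEFAULT_UNDETERMINED_TOKENS,
    missing_tokens=DEFAULT_MISSING_TOKENS,
    samples=None,
    targets=None,
    transpose: bool = False,
    sep=None,
) -> CqDataset:
    """Read a long- or wide-format Cq table into a :class:`CqDataset`.

    Parameters
    ----------
    path
        CSV/TSV file (delimiter autodetected unless ``sep`` given).
    format
        ``"long"``: columns ``sample_id``, ``target_id``, ``cq`` and
        optionally ``group``.  ``"wide"``: targets in rows, samples in
        columns, first column holding target ids (``transpose=True`` flips
        the orientation).
    lod
        Limit of detection; cells >= lod, or matching an undetermined token,
        become censored observations stored at the LOD.
    samples, targets
        Annotation tables (path, buffer or DataFrame).  ``samples`` must map
        sample_id -> group; ``targets`` may flag reference genes.
    """
    if format not in {"long", "wide"}:
        raise ValueError("format must be 'long' or 'wide'")
    undetermined_tokens = set(undetermined_tokens)
    missing_tokens = set(missing_tokens)

    if samples is not None and not isinstance(samples, pd.DataFrame):
        samples = pd.read_csv(samples, sep=None, engine="python").set_index("sample_id")
    if targets is not None and not isinstance(targets, pd.DataFrame):
        targets = pd.read_csv(targets, sep=None, engine="python").set_index("target_id")

    raw = _read_table(path, sep=sep)
    rows = []
    if format == "long":
        needed = {"sample_id", "target_id", "cq"}
        if not needed.issubset(raw.columns):
            raise CqValidationError(
                f"long format requires columns {sorted(needed)}; got {list(raw.columns)}"
            )
        for idx, rec in raw.iterrows():
            cq, cens, miss = _parse_cq_cell(
                rec["cq"], lod, undetermined_tokens, missing_tokens, f"row {idx + 2}"
            )
            if miss:
                continue
            row = {
                "sample_id": rec["sample_id"],
                "target_id": rec["target_id"],
                "cq": cq,
                "censored": cens,
            }
            if "group" in raw.columns and samples is None:
                row["group"] = rec["group"]
            rows.append(row)
    else:
        mat = raw.set_index(raw.columns[0])
        mat.index.name = "target_id"
        if transpose:
            mat = mat.T
            mat.index.name = "target_id"
        for tid, rec in mat.iterrows():
            for sid, value in rec.items():
                cq, cens, miss = _parse_cq_cell(
                    value, lod, undetermined_tokens, missing_tokens,
                    f"target {tid}, sample {sid}",
                )
                if miss:
                    continue
                rows.append(
                    {"sample_id": sid, "target_id": tid, "cq": cq, "censored": cens}
                )
    obs = pd.DataFrame(rows)
    if len(obs) == 0:
        raise CqValidationError("no observations parsed")
    return make_dataset(obs, lod, samples=samples, targets=targets)


def write_cq_table(dataset: CqDataset, path, undetermined_token="Undetermined") -> None:
    """Export a dataset in long format; censored wells become the sentinel
    token so that re-reading with the same LOD reproduces the dataset."""
    out = dataset.data.copy()
    out["cq"] = out["cq"].map(lambda v: f"{v:.10g}")
    out.loc[dataset.data["censored"], "cq"] = undetermined_token
    out[["sample_id", "target_id", "group", "cq"]].to_csv(path, index=False)


RESULT_COLUMNS = [
    "target_id", "delta_hat", "se", "wald_stat", "p_value", "p_adj",
    "fc", "fc_ci_low", "fc_ci_high", "n_censored_per_group",
]


def write_results(result: pd.DataFrame, path) -> None:
    """Write a differential-expression results table as TSV (10 significant
    digits, lossless round trip at 1e-9 relative)."""
    if len(result) == 0:
        raise ValueError("results table is empty")
    out = result.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[RESULT_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
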