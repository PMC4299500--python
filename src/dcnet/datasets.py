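"""Expression dataset container and tab-separated I/O.

The pipeline operates on log-intensity-like expression matrices laid out as
reporters (rows) by samples (columns), with a per-sample group label
(case/control, or elder/adult for aging data), a per-sample covariate table,
and an optional block of control probes used for confounder adjustment.
Missing entries are NaN, never silently zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset"]


@dataclass
class ExpressionDataset:
    """Reporters-by-samples expression matrix with sample annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Expression matrix, index = reporter IDs, columns = sample IDs.
        Missing entries are ``NaN``.
    groups : pandas.Series
        Group label per sample (e.g. ``"case"``/``"control"``); the index
        must equal ``values.columns``. No sample belongs to two groups by
        construction (one label per sample).
    covariates : pandas.DataFrame
        Per-sample covariate table (rows align 1:1 with sample columns).
    control_probes : pandas.DataFrame, optional
        Control-probe block (probes x samples), same sample columns.
    control_classes : pandas.Series, optional
        Probe-class label per control probe (index = control probe IDs).
    attrs : dict
        Free-form metadata (e.g. injected latent factors, pre-mask values).
    """

    values: pd.DataFrame
    groups: pd.Series
    covariates: pd.DataFrame
    control_probes: pd.DataFrame | None = None
    control_classes: pd.Series | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = list(self.values.columns)
        if list(self.groups.index) != samples:
            raise ValueError("group labels do not align with sample columns")
        if list(self.covariates.index) != samples:
            raise ValueError("covariate rows do not align with sample columns")
        if self.control_probes is not None:
            if list(self.control_probes.columns) != samples:
                raise ValueError("control probes do not align with sample columns")
            if self.control_classes is None or list(self.control_classes.index) != list(
                self.control_probes.index
            ):
                raise ValueError("control probe classes do not align with control probes")

    # -- basic views -----------------------------------------------------

    @property
    def reporters(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_names(self) -> list[str]:
        return sorted(self.groups.unique())

    def group_matrix(self, label: str) -> pd.DataFrame:
        """Expression submatrix of the samples carrying ``label``."""
        cols = self.groups.index[self.groups == label]
        if len(cols) == 0:
            raise KeyError(f"no samples in group {label!r}")
        return self.values.loc[:, cols]

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            values=self.values.copy(),
            groups=self.groups.copy(),
            covariates=self.covariates.copy(),
            control_probes=None if self.control_probes is None else self.control_probes.copy(),
            control_classes=None if self.control_classes is None else self.control_classes.copy(),
            attrs=dict(self.attrs),
        )

    # -- I/O -------------------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        """Write the dataset as tab-separated tables under ``path``.

        ``expression.tsv`` has reporter IDs in the first column and sample
        IDs in the header row; ``covariates.tsv`` carries the group label as
        an extra ``group`` column.
        """
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.values.rename_axis("reporter").to_csv(path / "expression.tsv", sep="\t")
        cov = self.covariates.copy()
        cov.insert(0, "group", self.groups)
        cov.rename_axis("sample").to_csv(path / "covariates.tsv", sep="\t")
        if self.control_probes is not None:
            cp = self.control_probes.copy()
            cp.insert(0, "probe_class", self.control_classes)
            cp.rename_axis("probe").to_csv(path / "control_probes.tsv", sep="\t")
        serializable = {k: v for k, v in self.attrs.items() if _jsonable(v)}
        (path / "attrs.json").write_text(json.dumps(serializable, indent=1))

    @classmethod
    def from_dir(cls, path: str | Path) -> "ExpressionDataset":
        path = Path(path)
        values = pd.read_csv(path / "expression.tsv", sep="\t", index_col=0)
        cov = pd.read_csv(path / "covariates.tsv", sep="\t", index_col=0)
        groups = cov.pop("group")
        control_probes = control_classes = None
        if (path / "control_probes.tsv").exists():
            cp = pd.read_csv(path / "control_probes.tsv", sep="\t", index_col=0)
            control_classes = cp.pop("probe_class")
            control_probes = cp
        attrs = {}
        if (path / "attrs.json").exists():
            attrs = json.loads((path / "attrs.json").read_text())
        return cls(values, groups, cov, control_probes, control_classes, attrs)


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def as_matrix(x) -> np.ndarray:
    """Coerce a DataFrame or array to a 2-D float ndarray."""
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float)
    return np.asarray(x, dtype=float)
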