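"""Decision-making-unit (DMU) panel container and CSV I/O.

A :class:`DMUPanel` holds, for ``n`` hospitals (or any DMUs), the input matrix
``X`` (n x p), the output matrix ``Y`` (n x q), optional environmental
covariates ``Z`` (n x r), unit identifiers and group labels.  Synthetic panels
additionally carry the true Farrell inefficiency ``true_delta`` used by the
parameter-recovery tests; the estimation path never reads it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class PanelValidationError(ValueError):
    """Raised when a DMU panel violates its structural invariants."""


@dataclass
class DMUPanel:
    ids: np.ndarray
    groups: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray | None = None
    input_names: list[str] | None = None
    output_names: list[str] | None = None
    covariate_names: list[str] | None = None
    true_delta: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.groups = np.asarray(self.groups)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.Z is not None:
            self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
            if self.Z.size == 0:
                self.Z = None
        if self.input_names is None:
            self.input_names = [f"x{k + 1}" for k in range(self.X.shape[1])]
        if self.output_names is None:
            self.output_names = [f"y{m + 1}" for m in range(self.Y.shape[1])]
        if self.Z is not None and self.covariate_names is None:
            self.covariate_names = [f"z{j + 1}" for j in range(self.Z.shape[1])]
        if self.true_delta is not None:
            self.true_delta = np.asarray(self.true_delta, dtype=float)
        self.validate()

    # -- structural invariants -------------------------------------------
    def validate(self) -> None:
        n = len(self.ids)
        if n < 1:
            raise PanelValidationError("panel must contain at least one unit")
        if len(np.unique(self.ids)) != n:
            raise PanelValidationError("unit ids must be unique")
        if len(self.groups) != n:
            raise PanelValidationError("groups length does not match ids")
        for name, mat in (("X", self.X), ("Y", self.Y)):
            if mat.shape[0] != n:
                raise PanelValidationError(f"{name} has {mat.shape[0]} rows, expected {n}")
            if not np.all(np.isfinite(mat)):
                raise PanelValidationError(f"{name} contains non-finite values")
            if np.any(mat < 0):
                raise PanelValidationError(f"{name} must be nonnegative")
        if not np.all(self.X.max(axis=1) > 0):
            bad = self.ids[self.X.max(axis=1) <= 0]
            raise PanelValidationError(f"units with all-zero inputs: {list(bad)}")
        if not np.all(self.Y.max(axis=1) > 0):
            bad = self.ids[self.Y.max(axis=1) <= 0]
            raise PanelValidationError(f"units with all-zero outputs: {list(bad)}")
        if self.Z is not None and self.Z.shape[0] != n:
            raise PanelValidationError("Z row count does not match ids")

    # -- convenience ------------------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.ids)

    @property
    def n_inputs(self) -> int:
        return self.X.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.Y.shape[1]

    @property
    def n_covariates(self) -> int:
        return 0 if self.Z is None else self.Z.shape[1]

    def group_labels(self) -> list:
        seen: dict = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def subset(self, mask: np.ndarray) -> "DMUPanel":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return DMUPanel(
            ids=self.ids[idx],
            groups=self.groups[idx],
            X=self.X[idx],
            Y=self.Y[idx],
            Z=None if self.Z is None else self.Z[idx],
            input_names=self.input_names,
            output_names=self.output_names,
            covariate_names=self.covariate_names,
            true_delta=None if self.true_delta is None else self.true_delta[idx],
            meta=dict(self.meta),
        )

    def by_group(self, group) -> "DMUPanel":
        return self.subset(self.groups == group)

    # -- I/O ---------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        data: dict = {"id": self.ids, "group": self.groups}
        for k, name in enumerate(self.input_names):
            data[name] = self.X[:, k]
        for m, name in enumerate(self.output_names):
            data[name] = self.Y[:, m]
        if self.Z is not None:
            for j, name in enumerate(self.covariate_names):
                data[name] = self.Z[:, j]
        if self.true_delta is not None:
            data["true_delta"] = self.true_delta
        return pd.DataFrame(data)

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the panel as UTF-8 comma-separated values.

        A sidecar ``<stem>.meta.json`` records column roles (and, for
        synthetic panels, the generating configuration) so the file round
        trips without guessing.
        """
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {
                "input_names": self.input_names,
                "output_names": self.output_names,
                "covariate_names": self.covariate_names or [],
                **self.meta,
            }
            path.with_suffix(".meta.json").write_text(
                json.dumps(meta, indent=2, sort_keys=True) + "\n"
            )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        inputs: list[str],
        outputs: list[str],
        covariates: list[str] | None = None,
        id_col: str = "id",
        group_col: str = "group",
    ) -> "DMUPanel":
        for col in [id_col, group_col, *inputs, *outputs, *(covariates or [])]:
            if col not in df.columns:
                raise PanelValidationError(f"missing column: {col!r}")
        for col in [*inputs, *outputs, *(covariates or [])]:
            if not np.issubdtype(df[col].dtype, np.number):
                raise PanelValidationError(f"column {col!r} is not numeric")
        return cls(
            ids=df[id_col].to_numpy(),
            groups=df[group_col].to_numpy(),
            X=df[inputs].to_numpy(float),
            Y=df[outputs].to_numpy(float),
            Z=df[covariates].to_numpy(float) if covariates else None,
            input_names=list(inputs),
            output_names=list(outputs),
            covariate_names=list(covariates) if covariates else None,
            true_delta=df["true_delta"].to_numpy(float) if "true_delta" in df else None,
        )

    @classmethod
    def from_csv(
        cls,
        path,
        inputs: list[str] | None = None,
        outputs: list[str] | None = None,
        covariates: list[str] | None = None,
        id_col: str = "id",
        group_col: str = "group",
    ) -> "DMUPanel":
        """Read a panel CSV.  Column roles come from arguments, from the
        sidecar ``.meta.json`` if present, or from ``x*/y*/z*`` prefixes."""
        path = Path(path)
        df = pd.read_csv(path)
        if inputs is None or outputs is None:
            sidecar = path.with_suffix(".meta.json")
            if sidecar.exists():
                meta = json.loads(sidecar.read_text())
                inputs = inputs or meta["input_names"]
                outputs = outputs or meta["output_names"]
                if covariates is None:
                    covariates = meta.get("covariate_names") or None
            else:
                inputs = inputs or [c for c in df.columns if c.startswith("x")]
                outputs = outputs or [c for c in df.columns if c.startswith("y")]
                if covariates is None:
                    covariates = [c for c in df.columns if c.startswith("z")] or None
        return cls.from_dataframe(df, inputs, outputs, covariates, id_col, group_col)
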