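"""Trait-based (traditional) morphometrics: 13 unitless ratios.

Traits are defined declaratively in a :class:`TraitCatalog` — ordered
``(name, numerator, denominator)`` entries whose expressions are sums and
products of named measurements (``**`` with an integer exponent is allowed,
e.g. ``standard_length**2``). The default catalog is a widely used
diet-and-locomotion set over 17 linear measures and 3 areas; every default
trait is a homogeneous ratio, so uniformly rescaling an individual (lengths
by c, areas by c^2) leaves all trait values unchanged. Editing the catalog is
a data change, not a code change.

No log transform or allometric correction is applied by default.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .shapes import MEASUREMENT_NAMES, MeasurementRecord, ShapeError

DEFAULT_TRAITS: tuple[tuple[str, str, str], ...] = (
    ("eye_size", "eye_diameter", "head_depth"),
    ("eye_position", "eye_height", "body_depth"),
    ("oral_gape_position", "mouth_height", "body_depth"),
    ("elongation", "standard_length", "body_depth"),
    ("head_length_ratio", "head_length", "standard_length"),
    ("peduncle_throttling", "caudal_fin_depth", "caudal_peduncle_depth"),
    ("caudal_fin_aspect", "caudal_fin_depth**2", "caudal_fin_area"),
    ("pectoral_position", "pectoral_insertion_height", "body_depth"),
    ("pectoral_fin_aspect", "pectoral_fin_length**2", "pectoral_fin_area"),
    ("dorsal_spine_ratio", "dorsal_spine_length", "body_depth"),
    ("body_surface_ratio", "body_area", "standard_length**2"),
    ("pectoral_surface_ratio", "pectoral_fin_area", "body_area"),
    ("caudal_surface_ratio", "caudal_fin_area", "body_area"),
)

_ALLOWED_NODES = (
    ast.Expression, ast.BinOp, ast.Add, ast.Mult, ast.Pow, ast.Name,
    ast.Constant, ast.Load, ast.UnaryOp, ast.USub,
)


def _names_in(expr: str) -> set[str]:
    return {
        node.id
        for node in ast.walk(ast.parse(expr, mode="eval"))
        if isinstance(node, ast.Name)
    }


def _check_expr(expr: str, schema: tuple[str, ...]) -> None:
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ShapeError(f"cannot parse trait expression {expr!r}: {exc}") from exc
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ShapeError(
                f"trait expression {expr!r}: only +, *, ** and measurement "
                f"names are allowed (found {type(node).__name__})"
            )
        if isinstance(node, ast.Name) and node.id not in schema:
            raise ShapeError(
                f"trait expression {expr!r} references unknown measurement "
                f"'{node.id}'"
            )


def _evaluate(expr: str, env: dict[str, np.ndarray]) -> np.ndarray:
    return eval(compile(ast.parse(expr, mode="eval"), "<trait>", "eval"),
                {"__builtins__": {}}, env)


@dataclass
class TraitCatalog:
    """Ordered declarative trait definitions over the measurement schema."""

    entries: tuple[tuple[str, str, str], ...] = DEFAULT_TRAITS
    schema: tuple[str, ...] = MEASUREMENT_NAMES

    def __post_init__(self) -> None:
        for name, num, den in self.entries:
            _check_expr(num, self.schema)
            _check_expr(den, self.schema)

    @property
    def trait_names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def required_measurements(self) -> set[str]:
        req: set[str] = set()
        for _, num, den in self.entries:
            req |= _names_in(num) | _names_in(den)
        return req

    @staticmethod
    def from_csv(path) -> "TraitCatalog":
        df = pd.read_csv(path)
        cols = {"trait_name", "numerator", "denominator"}
        if not cols <= set(df.columns):
            raise ShapeError(f"trait catalog CSV needs columns {sorted(cols)}")
        return TraitCatalog(
            entries=tuple(
                (r.trait_name, r.numerator, r.denominator) for r in df.itertuples()
            )
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.entries, columns=["trait_name", "numerator", "denominator"]
        ).to_csv(path, index=False)


def compute_traits(
    records: list[MeasurementRecord] | pd.DataFrame,
    catalog: TraitCatalog | None = None,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Evaluate the trait catalog per individual.

    Returns a DataFrame with columns ``id``, ``species`` and one column per
    trait, rows in input order. Missing measurements and zero denominators
    are reported with the offending individual named.
    """
    catalog = catalog or TraitCatalog()
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([{"id": r.id, "species": r.species} | r.values
                           for r in records])
    required = catalog.required_measurements()
    ids = df["id"].astype(str) if "id" in df.columns else df.index.astype(str)
    for name in sorted(required):
        if name not in df.columns or df[name].isna().any():
            if name not in df.columns:
                bad = ids.iloc[0]
            else:
                bad = ids[df[name].isna()].iloc[0]
            raise ShapeError(
                f"individual '{bad}' is missing measurement '{name}'"
            )
    env = {name: df[name].to_numpy(dtype=float) for name in required}
    out = pd.DataFrame(index=df.index)
    if "id" in df.columns:
        out["id"] = df["id"]
    if "species" in df.columns:
        out["species"] = df["species"]
    for name, num, den in catalog.entries:
        denom = _evaluate(den, env)
        denom = np.asarray(denom, dtype=float)
        zero = denom == 0.0
        if np.any(zero):
            bad = ids[zero].iloc[0]
            raise ShapeError(
                f"trait '{name}': zero denominator for individual '{bad}'"
            )
        val = np.asarray(_evaluate(num, env), dtype=float) / denom
        out[name] = np.log(val) if log_transform else val
    return out


def trait_matrix(traits: pd.DataFrame, catalog: TraitCatalog | None = None):
    """(individuals, traits) float matrix + trait names from a trait table."""
    catalog = catalog or TraitCatalog()
    names = catalog.trait_names
    return traits[names].to_numpy(dtype=float), names
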