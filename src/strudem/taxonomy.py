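"""Three-level variable hierarchy (variable -> combo -> composite) and
correlation-graph grouping of combo embeddings.

A :class:`Taxonomy` partitions individual lab variables into *combo*
variables (bundles of redundant measurements reported under different lab
names) and, per named *grouping strategy*, partitions combos into
*composite indices* (e.g. organ systems, or data-driven correlation
components).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Taxonomy",
    "GroupingConfig",
    "TaxonomyError",
    "correlation_grouping",
    "pancreas_panel",
    "toy_taxonomy",
]


class TaxonomyError(ValueError):
    """Raised when a taxonomy violates its partition invariants."""


@dataclass
class Taxonomy:
    """Hierarchical variable taxonomy.

    Parameters
    ----------
    variables
        Ordered level-1 identifiers (individual lab variables).
    combo_map
        Total map ``variable -> combo``; induces a partition of variables.
    strategies
        Named maps ``combo -> composite``; each must be a total partition
        of the combos.
    """

    variables: list[str]
    combo_map: dict[str, str]
    strategies: dict[str, dict[str, str]] = field(default_factory=dict)

    # -- derived views -------------------------------------------------
    @property
    def combos(self) -> list[str]:
        """Combo identifiers in first-appearance order over ``variables``."""
        seen: dict[str, None] = {}
        for v in self.variables:
            seen.setdefault(self.combo_map[v], None)
        return list(seen)

    def composites(self, strategy: str) -> list[str]:
        smap = self._strategy(strategy)
        seen: dict[str, None] = {}
        for c in self.combos:
            seen.setdefault(smap[c], None)
        return list(seen)

    def combo_members(self, combo: str) -> list[str]:
        return [v for v in self.variables if self.combo_map[v] == combo]

    def composite_members(self, strategy: str, composite: str) -> list[str]:
        """Combos belonging to ``composite`` under ``strategy``."""
        smap = self._strategy(strategy)
        return [c for c in self.combos if smap[c] == composite]

    def composite_variables(self, strategy: str, composite: str) -> list[str]:
        """Level-1 variables in the transitive closure of ``composite``."""
        combos = set(self.composite_members(strategy, composite))
        return [v for v in self.variables if self.combo_map[v] in combos]

    def _strategy(self, name: str) -> dict[str, str]:
        if name not in self.strategies:
            raise TaxonomyError(
                f"unknown grouping strategy {name!r}; have {sorted(self.strategies)}"
            )
        return self.strategies[name]

    # -- validation ----------------------------------------------------
    def validate(self) -> "Taxonomy":
        """Check all partition invariants; return self unchanged if valid."""
        if len(set(self.variables)) != len(self.variables):
            dup = sorted({v for v in self.variables if self.variables.count(v) > 1})
            raise TaxonomyError(f"duplicate variable identifiers: {dup}")
        missing = [v for v in self.variables if v not in self.combo_map]
        if missing:
            raise TaxonomyError(f"variables missing from combo_map: {missing[:5]}")
        extra = sorted(set(self.combo_map) - set(self.variables))
        if extra:
            raise TaxonomyError(f"combo_map keys not in variables: {extra[:5]}")
        combos = set(self.combo_map.values())
        for name, smap in self.strategies.items():
            uncovered = sorted(combos - set(smap))
            if uncovered:
                raise TaxonomyError(
                    f"strategy {name!r}: combos missing a composite: {uncovered[:5]}"
                )
            dangling = sorted(set(smap) - combos)
            if dangling:
                raise TaxonomyError(
                    f"strategy {name!r}: unknown combos assigned: {dangling[:5]}"
                )
            for comp in set(smap.values()):
                if not any(smap[c] == comp for c in combos):
                    raise TaxonomyError(f"strategy {name!r}: empty composite {comp!r}")
        return self

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "combo_map": dict(self.combo_map),
            "strategies": {k: dict(v) for k, v in self.strategies.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Taxonomy":
        return cls(
            variables=list(d["variables"]),
            combo_map=dict(d["combo_map"]),
            strategies={k: dict(v) for k, v in d.get("strategies", {}).items()},
        ).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Taxonomy":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        """Stable hash used to pin model checkpoints to their taxonomy."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class GroupingConfig:
    """Configuration for correlation-graph grouping of combo embeddings."""

    threshold: float = 0.3
    residual_name: str = "residual"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")


def correlation_grouping(
    combo_embeddings: np.ndarray,
    combo_names: list[str],
    config: GroupingConfig | None = None,
) -> dict[str, str]:
    """Bundle combos that are mutually correlated into composites.

    Pairwise Pearson correlations of the per-patient combo embeddings are
    thresholded (``|r| > threshold``) into a graph; each connected component
    of size >= 2 becomes a composite (``comp1``, ``comp2``, ... ordered by
    first member), and all isolated combos are pooled into one residual
    composite.

    Parameters
    ----------
    combo_embeddings
        Array of shape ``(n_patients, n_combos)``.
    combo_names
        Column labels, one per combo.
    config
        Threshold and residual-group name; defaults to threshold 0.3.

    Returns
    -------
    dict
        Total map ``combo -> composite``.
    """
    config = config or GroupingConfig()
    E = np.asarray(combo_embeddings, dtype=float)
    if E.ndim != 2 or E.shape[1] != len(combo_names):
        raise ValueError("combo_embeddings must be (patients x combos)")
    n_pat, n_combo = E.shape
    if n_combo < 2 or n_pat < 3:
        raise ValueError("need >= 2 combos and >= 3 patients")

    sd = E.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant combo column(s) treated as uncorrelated",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(E, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 0.0)

    adj = (np.abs(R) > config.threshold).astype(np.int8)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    sizes = np.bincount(labels, minlength=n_comp)
    mapping: dict[str, str] = {}
    next_id = 1
    comp_name: dict[int, str] = {}
    for j, name in enumerate(combo_names):
        lab = labels[j]
        if sizes[lab] >= 2:
            if lab not in comp_name:
                comp_name[lab] = f"comp{next_id}"
                next_id += 1
            mapping[name] = comp_name[lab]
        else:
            mapping[name] = config.residual_name
    return mapping


# ---------------------------------------------------------------------------
# Packaged fixture: the 206-variable / 32-combo pancreatic-cancer lab panel
# ---------------------------------------------------------------------------

# (combo name, organ-system composite) for all 32 combo variables.
_G1 = {
    "pct_neutrophils": "white blood cell group",
    "alt": "liver function group",
    "serum_albumin": "liver function group",
    "ast": "liver function group",
    "pct_basophils": "white blood cell group",
    "bilirubin_direct": "liver function group",
    "bilirubin_indirect": "liver function group",
    "alk_phos": "liver function group",
    "calcium": "kidney group",
    "pt": "liver function group",
    "rbc": "red blood cell group",
    "rdw": "red blood cell group",
    "sodium": "kidney group",
    "hba1c": "diabetes group",
    "potassium": "kidney group",
    "total_protein": "liver function group",
    "phosphorus": "kidney group",
    "platelets": "red blood cell group",
    "wbc": "white blood cell group",
    "chloride": "kidney group",
    "creatinine": "kidney group",
    "pct_eosinophils": "white blood cell group",
    "glucose": "diabetes group",
    "mcv": "red blood cell group",
    "pct_monocytes": "white blood cell group",
    "hemoglobin": "red blood cell group",
    "mch": "red blood cell group",
    "hematocrit": "red blood cell group",
    "pct_lymphocytes": "white blood cell group",
    "magnesium": "kidney group",
    "abs_neutrophils": "white blood cell group",
    "abs_basophils": "white blood cell group",
}

# Correlation-derived strategies: g2 thresholds |r| > 0.3 (3 composites, comp3
# residual), g3 thresholds |r| > 0.4 (7 composites, comp7 residual).
_G2_GROUPS = {
    "comp1": [
        "pct_neutrophils", "alt", "ast", "bilirubin_direct", "bilirubin_indirect",
        "alk_phos", "calcium", "pt", "phosphorus", "platelets", "wbc",
        "creatinine", "pct_eosinophils", "glucose", "mcv", "pct_monocytes",
        "mch", "hematocrit", "pct_lymphocytes", "abs_neutrophils",
    ],
    "comp2": ["sodium", "hba1c", "potassium", "total_protein", "chloride"],
    "comp3": [
        "serum_albumin", "pct_basophils", "rbc", "rdw", "hemoglobin",
        "magnesium", "abs_basophils",
    ],
}
_G3_GROUPS = {
    "comp1": [
        "pct_neutrophils", "wbc", "pct_eosinophils", "pct_monocytes",
        "pct_lymphocytes", "abs_neutrophils",
    ],
    "comp2": ["alt", "alk_phos"],
    "comp3": ["ast", "bilirubin_direct"],
    "comp4": ["pt", "platelets"],
    "comp5": ["sodium", "potassium", "chloride"],
    "comp6": ["mcv", "mch", "hematocrit"],
    "comp7": [
        "serum_albumin", "pct_basophils", "bilirubin_indirect", "calcium",
        "rbc", "rdw", "hba1c", "total_protein", "phosphorus", "creatinine",
        "glucose", "hemoglobin", "magnesium", "abs_basophils",
    ],
}


def pancreas_panel(n_variables: int = 206) -> Taxonomy:
    """The packaged lab-panel taxonomy: 206 variables, 32 combos, three
    grouping strategies (g1: 5 organ systems; g2: 3 correlation composites;
    g3: 7 correlation composites).

    Level-1 members are synthetic aliases (``alt_1``, ``alt_2``, ...)
    standing in for the redundant institutional lab names bundled into each
    combo; the combo and composite structure is the real panel structure.
    """
    combos = list(_G1)
    n_combos = len(combos)
    if n_variables < n_combos:
        raise ValueError(f"need at least {n_combos} variables")
    base, extra = divmod(n_variables, n_combos)
    sizes = [base + 1 if i < extra else base for i in range(n_combos)]
    variables: list[str] = []
    combo_map: dict[str, str] = {}
    for combo, size in zip(combos, sizes):
        for i in range(1, size + 1):
            name = f"{combo}_{i}"
            variables.append(name)
            combo_map[name] = combo
    g2 = {c: comp for comp, cs in _G2_GROUPS.items() for c in cs}
    g3 = {c: comp for comp, cs in _G3_GROUPS.items() for c in cs}
    tax = Taxonomy(
        variables=variables,
        combo_map=combo_map,
        strategies={"g1": dict(_G1), "g2": g2, "g3": g3},
    )
    return tax.validate()


def toy_taxonomy(n_variables: int = 10, n_combos: int = 5,
                 n_composites: int = 2, strategy: str = "g1") -> Taxonomy:
    """Small synthetic hierarchy for smoke runs and unit fixtures:
    variables assigned round-robin to combos, combos round-robin to
    composites named ``group_1 ... group_K``."""
    if not 1 <= n_composites <= n_combos <= n_variables:
        raise ValueError("need n_composites <= n_combos <= n_variables")
    variables = [f"var_{i + 1}" for i in range(n_variables)]
    combos = [f"combo_{j + 1}" for j in range(n_combos)]
    combo_map = {v: combos[i % n_combos] for i, v in enumerate(variables)}
    smap = {c: f"group_{j % n_composites + 1}" for j, c in enumerate(combos)}
    return Taxonomy(variables=variables, combo_map=combo_map,
                    strategies={strategy: smap}).validate()
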