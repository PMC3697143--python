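"""Activation maps and hierarchical embedded masking.

Voxelwise tests are computed band by band; display and multiplicity control
combine them spatially.  The omnibus test (identity contrasts) gates
everything: its per-band p maps are thresholded at P = .001 and OR-combined
into a single binary omnibus mask.  Inside that mask a stimulus-by-state
interaction test produces an *exclusion* mask; multivariate main effects
are then tested only where the omnibus passed and no interaction was seen,
and multivariate simple effects are further gated by the corresponding
main-effect rejections.  Univariate simple effects are deliberately gated
only by the omnibus mask — a less stringent criterion that eases comparison
with conventional time-domain t-maps.

Activation strength is displayed as a multiple-P-level label: each voxel is
annotated with the most stringent threshold of a descending ladder that its
combined p-value passes.  The combination rule across bands (default:
minimum p — the most significant band drives the label) is an explicit,
documented reconstruction; so is the interaction gating threshold
(defaulting to the omnibus .001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import ConfigurationError

__all__ = [
    "DEFAULT_P_LEVELS",
    "PLevelMask",
    "MaskHierarchy",
    "HierarchyConfig",
    "omnibus_mask",
    "multi_p_mask",
    "hierarchical_pipeline",
]

DEFAULT_P_LEVELS = (0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001)

# audit status codes
PASS, FAIL, NOT_REACHED = 1, 0, -1
_STATUS_NAMES = {PASS: "pass", FAIL: "fail", NOT_REACHED: "not-reached"}


def _stack_p_maps(p_maps_per_band) -> np.ndarray:
    arr = np.asarray(p_maps_per_band, dtype=float)
    if arr.shape[0] == 0:
        raise ConfigurationError("empty band list: need at least one p map")
    return arr


def omnibus_mask(p_maps_per_band, threshold: float = 0.001) -> np.ndarray:
    """Boolean-OR combination of per-band binary masks at a strict threshold.

    A voxel enters the mask iff ``p < threshold`` in at least one band.
    NaN p-values (degenerate voxels) never pass.
    """
    arr = _stack_p_maps(p_maps_per_band)
    with np.errstate(invalid="ignore"):
        return np.any(arr < threshold, axis=0)


@dataclass(frozen=True)
class PLevelMask:
    """Most-stringent-passed P level per voxel.

    ``level_index[v]`` is the index into ``levels`` of the smallest
    threshold the voxel's combined p-value is below, or -1 if it passes
    none (or lies outside the gating mask).
    """

    levels: tuple[float, ...]
    level_index: np.ndarray  # int array, -1 = unlabeled
    combined_p: np.ndarray
    contrast_name: str = ""
    band_rule: str = "min-across-bands"

    def level_of(self, voxel_index) -> float | None:
        idx = self.level_index[voxel_index]
        return None if idx < 0 else self.levels[idx]

    def legend(self) -> dict[int, float]:
        """Label value (1-based) -> P level, for sidecar legends."""
        return {i + 1: lev for i, lev in enumerate(self.levels)}


def multi_p_mask(
    p_maps_per_band,
    levels=DEFAULT_P_LEVELS,
    band_rule: str = "min-across-bands",
    gate: np.ndarray | None = None,
    contrast_name: str = "",
) -> PLevelMask:
    """Assign each voxel the most stringent P level its combined p passes.

    Band p-values are first combined per voxel (default rule: minimum
    across bands), then binned against the strictly descending level
    ladder: level ``L`` is assigned iff ``p < L`` and ``p`` is not below the
    next more stringent level.  Voxels failing every level — or outside the
    optional gating mask — are unlabeled (-1).
    """
    levels = tuple(float(l) for l in levels)
    if any(a <= b for a, b in zip(levels, levels[1:])):
        raise ConfigurationError("P levels must be strictly descending")
    arr = _stack_p_maps(p_maps_per_band)
    if band_rule == "min-across-bands":
        filled = np.where(np.isnan(arr), np.inf, arr)
        combined = filled.min(axis=0)
    else:
        raise ConfigurationError(f"unknown band combination rule {band_rule!r}")
    # number of ladder levels the voxel is below; most stringent passed wins
    n_passed = sum((combined < lev).astype(int) for lev in levels)
    level_index = n_passed - 1  # -1 where none passed
    if gate is not None:
        level_index = np.where(np.asarray(gate, dtype=bool), level_index, -1)
    return PLevelMask(
        levels=levels,
        level_index=level_index,
        combined_p=np.where(np.isinf(combined), np.nan, combined),
        contrast_name=contrast_name,
        band_rule=band_rule,
    )


@dataclass(frozen=True)
class HierarchyConfig:
    """Names and thresholds wiring the hierarchical masking stages.

    ``simple_effect_gates`` maps a stage-4 multivariate simple-effect test
    to the stage-3 state/stimulus-effect test whose rejections gate it.
    ``univariate_tests`` are gated only by the omnibus mask.
    """

    omnibus: str = "omnibus"
    interaction: str | None = "interaction"
    effect_tests: tuple[str, ...] = ()
    simple_effect_gates: dict[str, str] = field(default_factory=dict)
    univariate_tests: tuple[str, ...] = ()
    omnibus_threshold: float = 0.001
    interaction_threshold: float = 0.001
    effect_threshold: float = 0.001


@dataclass(frozen=True)
class MaskHierarchy:
    """Output of the hierarchical pipeline.

    ``effect_masks`` are subsets of the omnibus mask; multivariate
    main-effect masks additionally exclude interaction-significant voxels.
    ``audit`` records, per stage, a status code for every voxel
    (1 pass, 0 fail, -1 not reached).
    """

    omnibus_mask: np.ndarray
    interaction_mask: np.ndarray
    effect_masks: dict[str, np.ndarray]
    audit: dict[str, np.ndarray]

    def audit_table(self) -> pd.DataFrame:
        """Long-format audit trail: voxel, stage, status."""
        rows = []
        for stage, codes in self.audit.items():
            flat = np.asarray(codes).ravel()
            for v, code in enumerate(flat):
                rows.append((v, stage, _STATUS_NAMES[int(code)]))
        return pd.DataFrame(rows, columns=["voxel", "stage", "status"])


def _sig_any_band(p_maps, threshold: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.any(_stack_p_maps(p_maps) < threshold, axis=0)


def hierarchical_pipeline(
    p_maps: dict[str, np.ndarray],
    config: HierarchyConfig,
) -> MaskHierarchy:
    """Run the embedded-mask stages over per-contrast, per-band p maps.

    ``p_maps[name]`` stacks one p map per band (band axis first).  Stages:

    1. omnibus mask (OR over bands at ``omnibus_threshold``);
    2. interaction tested inside it, yielding an exclusion mask;
    3. multivariate state/stimulus effects inside (omnibus AND NOT
       interaction);
    4. multivariate simple effects gated by their stage-3 test's mask;
       univariate simple effects gated only by the omnibus mask.
    """
    if config.omnibus not in p_maps:
        raise ConfigurationError(f"missing omnibus p maps {config.omnibus!r}")
    omni = omnibus_mask(p_maps[config.omnibus], config.omnibus_threshold)
    audit: dict[str, np.ndarray] = {"omnibus": omni.astype(int)}

    if config.interaction is not None:
        if config.interaction not in p_maps:
            raise ConfigurationError(
                f"missing interaction p maps {config.interaction!r}"
            )
        inter_sig = _sig_any_band(p_maps[config.interaction], config.interaction_threshold)
        interaction = omni & inter_sig
        audit["interaction"] = np.where(omni, inter_sig.astype(int), NOT_REACHED)
    else:
        interaction = np.zeros_like(omni)
        audit["interaction"] = np.where(omni, FAIL, NOT_REACHED)
    main_gate = omni & ~interaction

    effect_masks: dict[str, np.ndarray] = {}
    for name in config.effect_tests:
        if name not in p_maps:
            raise ConfigurationError(f"missing effect-test p maps {name!r}")
        sig = _sig_any_band(p_maps[name], config.effect_threshold)
        effect_masks[name] = main_gate & sig
        audit[name] = np.where(main_gate, sig.astype(int), NOT_REACHED)

    for name, gate_name in config.simple_effect_gates.items():
        if name not in p_maps:
            raise ConfigurationError(f"missing simple-effect p maps {name!r}")
        if gate_name not in effect_masks:
            raise ConfigurationError(
                f"simple effect {name!r} gated by unknown test {gate_name!r}"
            )
        gate = effect_masks[gate_name]
        sig = _sig_any_band(p_maps[name], config.effect_threshold)
        effect_masks[name] = gate & sig
        audit[name] = np.where(gate, sig.astype(int), NOT_REACHED)

    for name in config.univariate_tests:
        if name not in p_maps:
            raise ConfigurationError(f"missing univariate p maps {name!r}")
        sig = _sig_any_band(p_maps[name], config.effect_threshold)
        effect_masks[name] = omni & sig
        audit[name] = np.where(omni, sig.astype(int), NOT_REACHED)

    return MaskHierarchy(
        omnibus_mask=omni,
        interaction_mask=interaction,
        effect_masks=effect_masks,
        audit=audit,
    )
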