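"""Parameter sweeps over coupling strengths and phase-diagram assembly.

A :class:`SweepPlan` takes a base configuration, lists of values for the
swept couplings (typically the CT–CT exclusion β_φ and a chromatin-type
coupling β_ψ), and a replicate count.  Every (grid point, replicate)
run gets a distinct deterministic seed derived from the plan seed, so a
sweep is exactly reproducible (bitwise for noise-off runs).

Each endpoint is classified with :func:`melon4d.analysis.classify_morphology`;
the consensus regime per grid point is the modal call across replicates
(ties → ``"mixed"``).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import (MorphologyRule, classify_morphology, label_droplets)
from .config import RunConfig, load_config
from .io import run_from_config

__all__ = ["SweepPlan", "SweepError", "run_sweep", "classify_final_state",
           "DEFAULT_CORNER_SWEEP"]

logger = logging.getLogger(__name__)

#: 2×2 corner sweep spanning the qualitative regimes of the
#: (β_φ, β_ψ) phase diagram: low CT exclusion (strongly intermingling
#: territories) vs high (well-separated territories), crossed with
#: weak/strong chromatin-type coupling.
DEFAULT_CORNER_SWEEP = {"beta_phi": [10.0, 80.0], "beta_psi1": [0.1, 4.5]}


class SweepError(RuntimeError):
    """Every run of a sweep failed."""


@dataclass
class SweepPlan:
    """Cartesian sweep description.

    ``swept`` maps parameter names (fields of the config's parameters
    section) to value lists.  ``reduced_resolution`` divides the base
    mesh per axis (default 4, the desk-scale sweep resolution).
    """

    base: RunConfig
    swept: Dict[str, Sequence[float]]
    n_replicates: int = 1
    seed: int = 0
    reduced_resolution: Optional[int] = 4
    threshold: float = 0.5
    rule: MorphologyRule = dc_field(default_factory=MorphologyRule)

    def points(self) -> List[Dict[str, float]]:
        names = list(self.swept)
        return [dict(zip(names, combo))
                for combo in itertools.product(*(self.swept[n]
                                                 for n in names))]

    def run_seed(self, point_index: int, replicate: int) -> int:
        ss = np.random.SeedSequence(entropy=self.seed,
                                    spawn_key=(point_index, replicate))
        return int(ss.generate_state(1)[0] % (2 ** 31))


def classify_final_state(traj, cfg: RunConfig, threshold: float = 0.5,
                         rule: MorphologyRule = MorphologyRule()):
    """Label HC droplets of the final state and classify the morphology."""
    grid = cfg.build_grid()
    geom = cfg.build_geometry()
    state = traj.final_state
    sets = []
    phi = state.phi
    ds1 = label_droplets(state.psi1, grid, threshold, subtype="fHC", phi=phi)
    sets.append(ds1)
    if cfg.seeds.chc_fraction > 0 or state.psi2.max() >= threshold:
        sets.append(label_droplets(state.psi2, grid, threshold,
                                   subtype="cHC", phi=phi))
    call = classify_morphology(sets, phi, geom, grid, rule)
    return call, sets


def run_sweep(plan: SweepPlan) -> pd.DataFrame:
    """Execute the plan; one row per (grid point, replicate).

    Columns: the swept parameter values, replicate index, seed, regime,
    droplet statistics and final total energy.  Failed runs are recorded
    with ``regime="error"`` and the sweep continues; if every run fails
    a :class:`SweepError` is raised.  A ``consensus`` attribute
    (DataFrame) carries the modal regime per point.
    """
    rows = []
    n_ok = 0
    for p_idx, point in enumerate(plan.points()):
        for rep in range(plan.n_replicates):
            seed = plan.run_seed(p_idx, rep)
            overrides: Dict[str, dict] = {
                "parameters": dict(point),
                "integrator": {"rng_seed": seed},
                "output": {"directory": None},
            }
            if plan.reduced_resolution:
                overrides["grid"] = {
                    "resolution_divisor": plan.reduced_resolution}
            row: Dict[str, object] = dict(point)
            row.update({"replicate": rep, "seed": seed})
            try:
                cfg = load_config(text=plan.base.to_yaml(),
                                  overrides=overrides)
                traj = run_from_config(cfg)
                call, sets = classify_final_state(traj, cfg, plan.threshold,
                                                  plan.rule)
                row.update({
                    "regime": call.regime or "undefined",
                    "n_droplets": call.evidence.get("n_droplets", 0),
                    "cross_ct_spanning":
                        call.evidence.get("cross_ct_spanning", np.nan),
                    "mean_centroid_elliptic_radius":
                        call.evidence.get("mean_centroid_elliptic_radius",
                                          np.nan),
                    "total_energy": traj.total_energies[-1],
                })
                n_ok += 1
            except Exception as exc:            # noqa: BLE001 — record & continue
                logger.warning("sweep point %s replicate %d failed: %s",
                               point, rep, exc)
                row.update({"regime": "error", "error": str(exc)})
            rows.append(row)
    if n_ok == 0:
        raise SweepError("all sweep runs failed")
    table = pd.DataFrame(rows)

    swept_names = list(plan.swept)

    def consensus(group: pd.DataFrame) -> str:
        counts = group["regime"].value_counts()
        top = counts[counts == counts.max()]
        return top.index[0] if len(top) == 1 else "mixed"

    cons = (table.groupby(swept_names)
            .apply(consensus, include_groups=False)
            .rename("consensus_regime").reset_index())
    table.attrs["consensus"] = cons
    return table
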