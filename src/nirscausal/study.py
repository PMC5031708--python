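"""Cohort-level effective-connectivity study: model and results objects.

:class:`ConnectivityStudy` is built from per-participant, per-condition
Granger weights (one value per directed edge) plus ages; ``fit()`` runs the
per-edge repeated-measures ANOVA with bootstrap-averaged effect sizes and
the condition-scramble permutation rule, and returns a
:class:`ConnectivityStudyResults` carrying the long-format edge table,
``summary()``, and the per-effect significant-edge networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PreconditionError
from .gca import CausalMap
from .groupstats import (
    EFFECTS,
    NullStat,
    RaceAgeAnova,
)
from .netreport import GCNetwork, assemble_network

__all__ = ["ConnectivityStudy", "ConnectivityStudyResults"]


class ConnectivityStudy:
    """Edge-wise group model of a two-condition connectivity cohort.

    Parameters
    ----------
    weights_own, weights_other : ndarray, shape (N, E)
        Granger weight of each of E directed edges for each of N
        participants, per condition.
    ages : ndarray, shape (N,)
        Ages in years.
    edges : sequence of (from_ch, to_ch)
        Channel-id pair per column of the weight matrices.
    """

    def __init__(self, weights_own, weights_other, ages,
                 edges: Sequence[tuple[int, int]]):
        self.weights_own = np.asarray(weights_own, dtype=float)
        self.weights_other = np.asarray(weights_other, dtype=float)
        self.ages = np.asarray(ages, dtype=float)
        self.edges = [tuple(int(c) for c in e) for e in edges]
        n, e = self.weights_own.shape
        if self.weights_other.shape != (n, e) or len(self.ages) != n:
            raise PreconditionError("weight matrices and ages must align")
        if len(self.edges) != e:
            raise PreconditionError("edges must match weight columns")

    @classmethod
    def from_causal_maps(cls, maps: Sequence[CausalMap]) -> "ConnectivityStudy":
        """Assemble the study from one :class:`CausalMap` per participant per
        condition.  Edges with a missing weight for any participant are
        dropped (degenerate channels)."""
        by_pid: dict[str, dict[str, CausalMap]] = {}
        for m in maps:
            by_pid.setdefault(m.participant_id, {})[m.condition] = m
        pids = sorted(by_pid)
        incomplete = [p for p in pids if set(by_pid[p]) != {"own", "other"}]
        if incomplete:
            raise PreconditionError(f"participants missing a condition: {incomplete}")
        n_ch = maps[0].n_channels
        all_edges = [(i + 1, j + 1) for i in range(n_ch) for j in range(n_ch) if i != j]
        own = np.stack([
            np.array([by_pid[p]["own"].weights[i - 1, j - 1] for i, j in all_edges])
            for p in pids
        ])
        other = np.stack([
            np.array([by_pid[p]["other"].weights[i - 1, j - 1] for i, j in all_edges])
            for p in pids
        ])
        ages = np.array([by_pid[p]["own"].age for p in pids], dtype=float)
        keep = np.isfinite(own).all(axis=0) & np.isfinite(other).all(axis=0)
        edges = [e for e, k in zip(all_edges, keep) if k]
        return cls(own[:, keep], other[:, keep], ages, edges)

    @property
    def nobs(self) -> int:
        return len(self.ages)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def fit(
        self,
        b_boot: int = 10_000,
        b_perm: int = 10_000,
        frac: float = 0.5,
        seed: int | None = 0,
        null_stat: NullStat = "averaged",
        b_inner: int = 100,
    ) -> "ConnectivityStudyResults":
        """Run the full edge-level inference over every edge.

        Seeding: one RNG substream per edge, spawned from ``seed``, so the
        result is independent of any parallel scheduling of edges.
        """
        master = np.random.SeedSequence(seed if seed is not None else 0)
        streams = master.spawn(self.n_edges)
        rows = []
        for k, (edge, ss) in enumerate(zip(self.edges, streams)):
            model = RaceAgeAnova(self.weights_own[:, k],
                                 self.weights_other[:, k], self.ages)
            res = model.fit(b_boot=b_boot, b_perm=b_perm, frac=frac,
                            seed=np.random.default_rng(ss),
                            null_stat=null_stat, b_inner=b_inner)
            for effect in EFFECTS:
                eff = res.effects[effect]
                rows.append({
                    "from": edge[0], "to": edge[1], "effect": effect,
                    "F": eff.F, "df1": eff.df1, "df2": eff.df2,
                    "p": eff.p, "eta2": eff.eta2,
                    "boot_mean_eta2": res.boot_mean_eta2[effect],
                    "perm_p": res.perm_p[effect],
                    "significant": res.significant[effect],
                    "nore_r": res.nore_r, "nore_p": res.nore_p,
                })
        table = pd.DataFrame(rows)
        return ConnectivityStudyResults(
            model=self,
            table=table,
            params={"b_boot": b_boot, "b_perm": b_perm, "frac": frac,
                    "seed": seed, "null_stat": null_stat, "b_inner": b_inner},
        )


@dataclass
class ConnectivityStudyResults:
    """Long-format edge statistics plus network assembly helpers."""

    model: ConnectivityStudy
    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def significant_edges(self, effect: str) -> list[tuple[int, int]]:
        sub = self.table[(self.table["effect"] == effect) & self.table["significant"]]
        return [(int(r["from"]), int(r["to"])) for _, r in sub.iterrows()]

    def network(self, effect: str) -> GCNetwork:
        return assemble_network(
            self.table, effect,
            weights_own=self.model.weights_own,
            weights_other=self.model.weights_other,
            ages=self.model.ages,
            edges=self.model.edges,
        )

    def summary(self) -> str:
        lines = [
            "Connectivity study: race x continuous-age edge inference",
            f"N participants: {self.model.nobs}   directed edges: {self.model.n_edges}",
            f"resampling: {self.params}",
        ]
        for effect in EFFECTS:
            n_sig = len(self.significant_edges(effect))
            lines.append(f"significant {effect:<12} edges: {n_sig}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        header = "# " + " ".join(f"{k}={v}" for k, v in self.params.items())
        with open(path, "w") as fh:
            fh.write(header + "\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
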