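"""Demographic models: populations, timed events, migration, and the
three-spruce preset.

Time is specified in *years ago*; the per-generation coalescent clock uses
``generation_time`` (years/generation) to convert, quantizing event times to
whole generations (floor).  Population sizes are diploid effective sizes.

Events, interpreted backward in time:

* :class:`SizeChange` — the population's size becomes ``size`` for all times
  older than ``time_years``.
* :class:`Join` — lineages of ``derived`` merge into ``ancestral`` (the
  forward-time split of ``derived`` from ``ancestral``).
* :class:`Pulse` — each lineage in ``recipient`` jumps to ``donor`` with
  probability ``proportion`` (the forward-time admixture pulse donating
  ``proportion`` of the recipient's ancestry).

Joins into a population that has itself already merged are redirected to the
current representative, so event schedules stay valid when single event
times are moved around during fitting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml


@dataclass(frozen=True)
class Population:
    name: str
    size: float  # present-day diploid N_e

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError(f"population {self.name}: size must be > 0")


@dataclass(frozen=True)
class SizeChange:
    time_years: float
    pop: str
    size: float

    def __post_init__(self):
        if self.time_years < 0 or self.size <= 0:
            raise ValueError("size change needs time >= 0 and size > 0")


@dataclass(frozen=True)
class Join:
    time_years: float
    derived: str
    ancestral: str

    def __post_init__(self):
        if self.time_years < 0:
            raise ValueError("join time must be >= 0")


@dataclass(frozen=True)
class Pulse:
    time_years: float
    recipient: str
    donor: str
    proportion: float

    def __post_init__(self):
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("pulse proportion must be in [0, 1]")
        if self.time_years < 0:
            raise ValueError("pulse time must be >= 0")


# event type codes used by the simulation kernel
EV_SIZE, EV_JOIN, EV_PULSE = 0, 1, 2


@dataclass
class DemographicModel:
    """Populations + timed events + symmetric migration + mutation clock."""

    populations: list[Population]
    events: list = field(default_factory=list)
    migration: dict = field(default_factory=dict)  # (popA, popB) -> per-gen prob, symmetric
    mu_per_year: float = 1.1e-9
    generation_time: float = 25.0

    def __post_init__(self):
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        self._index = {n: i for i, n in enumerate(names)}
        if self.generation_time <= 0:
            raise ValueError("generation_time must be > 0")
        self._check_tree()

    # -- helpers -----------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [p.name for p in self.populations]

    def index(self, name: str) -> int:
        return self._index[name]

    def generations(self, years: float) -> float:
        """Years ago → whole generations ago (floor quantization)."""
        return float(np.floor(years / self.generation_time))

    def _check_tree(self) -> None:
        """Joins must leave exactly one root population."""
        alive = set(self.names)
        for ev in sorted(self.events, key=lambda e: e.time_years):
            if isinstance(ev, Join):
                if ev.derived in alive:
                    alive.discard(ev.derived)
        if len(alive) != 1:
            raise ValueError(f"joins must reduce the populations to one root; got {sorted(alive)}")

    # -- kernel compilation ------------------------------------------------
    def compile(self):
        """Flatten to arrays consumed by the simulation kernel.

        Returns dict with sizes0, ev_time (generations, ascending, stable),
        ev_type/ev_a/ev_b/ev_x, and the migration matrix.
        """
        P = len(self.populations)
        sizes0 = np.array([p.size for p in self.populations], dtype=np.float64)
        evs = sorted(enumerate(self.events), key=lambda t: (self.generations(t[1].time_years), t[0]))
        n = len(evs)
        ev_time = np.zeros(n)
        ev_type = np.zeros(n, dtype=np.int8)
        ev_a = np.zeros(n, dtype=np.int32)
        ev_b = np.full(n, -1, dtype=np.int32)
        ev_x = np.zeros(n)
        for r, (_, ev) in enumerate(evs):
            ev_time[r] = self.generations(ev.time_years)
            if isinstance(ev, SizeChange):
                ev_type[r], ev_a[r], ev_x[r] = EV_SIZE, self.index(ev.pop), ev.size
            elif isinstance(ev, Join):
                ev_type[r], ev_a[r], ev_b[r] = EV_JOIN, self.index(ev.derived), self.index(ev.ancestral)
            elif isinstance(ev, Pulse):
                ev_type[r] = EV_PULSE
                ev_a[r], ev_b[r], ev_x[r] = self.index(ev.recipient), self.index(ev.donor), 0
                ev_x[r] = ev.proportion
            else:
                raise TypeError(f"unknown event {ev!r}")
        mig = np.zeros((P, P))
        for (a, b), m in self.migration.items():
            ia, ib = self.index(a), self.index(b)
            mig[ia, ib] = mig[ib, ia] = m
        return {
            "sizes0": sizes0,
            "ev_time": ev_time,
            "ev_type": ev_type,
            "ev_a": ev_a,
            "ev_b": ev_b,
            "ev_x": ev_x,
            "mig": mig,
        }

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "populations": [{"name": p.name, "size": float(p.size)} for p in self.populations],
            "events": [],
            "migration": [
                {"pops": list(k), "rate": float(v)} for k, v in self.migration.items()
            ],
            "mu_per_year": float(self.mu_per_year),
            "generation_time": float(self.generation_time),
        }
        for ev in self.events:
            d = dataclasses.asdict(ev)
            d["kind"] = type(ev).__name__.lower()
            doc["events"].append(d)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DemographicModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        kinds = {"sizechange": SizeChange, "join": Join, "pulse": Pulse}
        events = []
        for d in doc.get("events", []):
            kind = kinds[d.pop("kind")]
            events.append(kind(**d))
        return cls(
            populations=[Population(**p) for p in doc["populations"]],
            events=events,
            migration={tuple(m["pops"]): m["rate"] for m in doc.get("migration", [])},
            mu_per_year=doc.get("mu_per_year", 1.1e-9),
            generation_time=doc.get("generation_time", 25.0),
        )


# ---------------------------------------------------------------------------
# The fitted three-spruce model
# ---------------------------------------------------------------------------

#: Point estimates of the fitted model (diploid sizes, years).
SPRUCE_PARAMS = dict(
    n_omo=78.0,
    n_obo=35_498.0,
    n_hyb=390.0,
    n_alp=5_982.0,
    n_car=8_043.0,
    n_fen=7_540.0,
    t_omo_split=22_875_400.0,   # P. omorika vs (P. obovata + P. abies)
    t_obo_abies=17_600_050.0,   # P. obovata vs P. abies
    t_fac=15_274_375.0,         # Fennoscandian vs (Alpine + Carpathian)
    t_ac=15_272_700.0,          # Alpine vs Carpathian
    t_adm=103_150.0,            # ancient pulse P. obovata -> FEN
    alpha_adm=0.17,             # proportion of that pulse
    t_hyb=1_600.0,              # founding of the hybrid population
    alpha_hyb=0.5,              # hybrid ancestry share from P. obovata
    t_bot_abies=12_850.0,       # shared bottleneck of the three P. abies domains
    t_bot_omo=2_775.0,          # P. omorika bottleneck
    n_anc_abies=2.5e5,          # pre-bottleneck P. abies domain size (bracket 2.5e5-5.7e5)
    n_obo_old=5.6e6,            # P. obovata size older than the ancient pulse
    n_fen_old=6.0e5,            # FEN size older than the ancient pulse
    omo_contraction=3_200.0,    # fold-change of the P. omorika bottleneck
    m_abies=1e-6,               # migration among ALP/CAR/FEN, per lineage per generation
)


def spruce_model(generation_time: float = 25.0, mu_per_year: float = 1.1e-9, **overrides) -> DemographicModel:
    """The fitted demographic model for *P. omorika* / *P. obovata* / *P. abies*.

    Any key of :data:`SPRUCE_PARAMS` may be overridden, which is how single
    parameters are freed during fitting.  Event times are in years ago and do
    not depend on ``generation_time``; diploid sizes scale by
    ``25 / generation_time`` so that the per-year coalescent process implied
    by the data stays fixed (doubling the generation time halves every N_e
    while leaving year-denominated times unchanged).
    """
    p = dict(SPRUCE_PARAMS)
    unknown = set(overrides) - set(p)
    if unknown:
        raise KeyError(f"unknown spruce parameters: {sorted(unknown)}")
    p.update(overrides)
    s = 25.0 / generation_time  # size rescaling for non-default generation time

    pops = [
        Population("OMO", p["n_omo"] * s),
        Population("OBO", p["n_obo"] * s),
        Population("HYB", p["n_hyb"] * s),
        Population("ALP", p["n_alp"] * s),
        Population("CAR", p["n_car"] * s),
        Population("FEN", p["n_fen"] * s),
    ]
    events = [
        # hybrid founded with alpha_hyb ancestry from OBO, remainder from FEN
        Pulse(p["t_hyb"], "HYB", "OBO", p["alpha_hyb"]),
        Join(p["t_hyb"], "HYB", "FEN"),
        # P. omorika bottleneck: pre-bottleneck size = fold-change x current
        SizeChange(p["t_bot_omo"], "OMO", p["n_omo"] * p["omo_contraction"] * s),
        # shared LGM bottleneck of the three P. abies domains
        SizeChange(p["t_bot_abies"], "ALP", p["n_anc_abies"] * s),
        SizeChange(p["t_bot_abies"], "CAR", p["n_anc_abies"] * s),
        SizeChange(p["t_bot_abies"], "FEN", p["n_anc_abies"] * s),
        # ancient pulse from P. obovata into FEN, when both were much larger
        SizeChange(p["t_adm"], "OBO", p["n_obo_old"] * s),
        SizeChange(p["t_adm"], "FEN", p["n_fen_old"] * s),
        Pulse(p["t_adm"], "FEN", "OBO", p["alpha_adm"]),
        # species/domain splits (backward joins)
        Join(p["t_ac"], "ALP", "CAR"),
        Join(p["t_fac"], "CAR", "FEN"),
        Join(p["t_obo_abies"], "FEN", "OBO"),
        Join(p["t_omo_split"], "OBO", "OMO"),
    ]
    migration = {}
    if p["m_abies"] > 0:
        for a, b in (("ALP", "CAR"), ("ALP", "FEN"), ("CAR", "FEN")):
            migration[(a, b)] = p["m_abies"]
    return DemographicModel(
        populations=pops,
        events=events,
        migration=migration,
        mu_per_year=mu_per_year,
        generation_time=generation_time,
    )
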