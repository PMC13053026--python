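"""Parametric sender and receiver agents for synthetic dyads.

These agents generate game logs whose statistical structure mirrors what
the analysis pipeline assumes about human dyads:

* **Iconic anchoring.**  A sender who sees colors aims each production at
  a fixed, referent-specific *anchor* point (the spot whose color evokes
  the referent — yellow for banana, red for strawberry, ...) plus
  isotropic Gaussian motor noise.  Productions for a referent are
  therefore tightly clustered across the whole game.
* **Drifting arbitrary conventions.**  A sender who sees only a dot has
  no anchor; they maintain an arbitrary convention point per referent
  that drifts a little every time it is reused and is occasionally
  forgotten and resampled uniformly.  Productions wander.
* **Exemplar learning under memory load.**  The receiver stores recent
  (view, referent) feedback pairs — as fuzzy copies, perturbed by
  encoding noise — and classifies a new view by kernel similarity to the
  stored exemplars.  The encoding noise is what makes a set of six
  arbitrary signals genuinely hard to hold in memory.
* **Iconic prior.**  A receiver who sees *colors* additionally scores
  each referent by how close the viewed color is to that referent's
  anchor color; a receiver who sees dots cannot exploit iconicity and
  this prior is forced off.

The anchors stand in for the qualitative outcome of a color-association
norming survey; they sit at well-separated pad positions whose colors are
canonical for the six referents, and are config-overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .engine import GameConfig, GameLog, REFERENTS, run_game
from .signal_space import CONDITIONS, PadPoint, SignalView, pad_to_lab

__all__ = [
    "DEFAULT_ANCHORS",
    "SenderParams",
    "ReceiverParams",
    "Sender",
    "Receiver",
    "generate_cohort",
    "make_signal_bank",
    "estimate_sigma_motor",
]

#: Default iconic anchor positions (pad coordinates, v = 0 at the bottom).
#: Chosen from the colorspace geometry: the bottom edge sweeps
#: red → orange → yellow → green left to right at L* = 75, while the top
#: half darkens towards blues and purples.  All anchors sit >= 0.08 from
#: every edge so that motor noise is effectively untruncated.
DEFAULT_ANCHORS: Dict[str, PadPoint] = {
    "strawberry": PadPoint(0.08, 0.35),  # saturated red
    "orange": PadPoint(0.20, 0.15),      # orange
    "banana": PadPoint(0.50, 0.08),      # yellow
    "kiwi": PadPoint(0.90, 0.30),        # green
    "blueberry": PadPoint(0.60, 0.92),   # dark blue
    "eggplant": PadPoint(0.25, 0.88),    # dark purple
}


def _validate_anchors(anchors: Mapping[str, PadPoint]) -> Dict[str, PadPoint]:
    if set(anchors) != set(REFERENTS):
        raise ValueError("anchors must cover exactly the six referents")
    names = list(anchors)
    for i, r1 in enumerate(names):
        for r2 in names[i + 1:]:
            a, b = anchors[r1], anchors[r2]
            if a.u == b.u and a.v == b.v:
                raise ValueError(f"anchors for {r1} and {r2} coincide")
    return dict(anchors)


@dataclass(frozen=True)
class SenderParams:
    """Sender model parameters (pad units).

    sigma_motor : SD of isotropic Gaussian motor noise around the aimed
        point (applies in every condition).
    sigma_drift : per-reuse SD of the random walk an arbitrary convention
        takes when the sender cannot see colors.
    p_forget : per-reuse probability that an arbitrary convention is
        forgotten and resampled uniformly on the pad.
    anchors : referent → iconic anchor point; defaults to
        :data:`DEFAULT_ANCHORS`.
    """

    sigma_motor: float = 0.03
    sigma_drift: float = 0.10
    p_forget: float = 0.10
    anchors: Optional[Mapping[str, PadPoint]] = None

    def __post_init__(self) -> None:
        if self.sigma_motor < 0 or self.sigma_drift < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.p_forget <= 1.0:
            raise ValueError("p_forget must lie in [0, 1]")


@dataclass(frozen=True)
class ReceiverParams:
    """Receiver model parameters.

    memory_capacity : max exemplars stored per referent (oldest evicted).
    lambda_prior : weight of the iconic prior for *color* views; forced to
        0 whenever the receiver sees dots.
    epsilon_guess : lapse probability (uniform random guess).
    tau_pad / tau_lab : Gaussian-kernel bandwidths for similarity in dot
        (pad-unit) and color (CIELAB) space respectively.
    sigma_memory_pad / sigma_memory_lab : SD of exemplar *encoding noise*
        (pad units / CIELAB units).  Remembered signals are fuzzy copies
        of what was seen; this is the memory-load bottleneck that makes a
        set of six arbitrary signals hard to hold, while the iconic prior
        — which needs no memory — is unaffected.
    """

    memory_capacity: int = 4
    lambda_prior: float = 0.6
    epsilon_guess: float = 0.05
    tau_pad: float = 0.12
    tau_lab: float = 45.0
    sigma_memory_pad: float = 0.18
    sigma_memory_lab: float = 20.0
    anchors: Optional[Mapping[str, PadPoint]] = None

    def __post_init__(self) -> None:
        if self.memory_capacity < 1:
            raise ValueError("memory_capacity must be >= 1")
        if not 0.0 <= self.lambda_prior <= 1.0:
            raise ValueError("lambda_prior must lie in [0, 1]")
        if not 0.0 <= self.epsilon_guess <= 1.0:
            raise ValueError("epsilon_guess must lie in [0, 1]")
        if self.tau_pad <= 0 or self.tau_lab <= 0:
            raise ValueError("kernel bandwidths must be positive")
        if self.sigma_memory_pad < 0 or self.sigma_memory_lab < 0:
            raise ValueError("memory noise SDs must be non-negative")


class Sender:
    """Stateful sender agent; see module docstring for the model."""

    def __init__(self, params: Optional[SenderParams] = None) -> None:
        self.params = params or SenderParams()
        self.anchors = _validate_anchors(self.params.anchors or DEFAULT_ANCHORS)
        self._conventions: Dict[str, Tuple[float, float]] = {}

    def _noisy(self, u: float, v: float, sigma: float, rng: np.random.Generator) -> PadPoint:
        if sigma == 0.0:
            return PadPoint(u, v)
        # truncate to the unit square by rejection; anchors sit well inside
        # the pad, so rejections are vanishingly rare there
        for _ in range(100):
            uu = u + sigma * rng.standard_normal()
            vv = v + sigma * rng.standard_normal()
            if 0.0 <= uu <= 1.0 and 0.0 <= vv <= 1.0:
                return PadPoint(uu, vv)
        return PadPoint(min(1.0, max(0.0, uu)), min(1.0, max(0.0, vv)))

    def produce(self, referent: str, sees_color: bool, rng: np.random.Generator) -> PadPoint:
        """Produce a pad point for ``referent``.

        With ``sees_color`` the point is the iconic anchor plus motor
        noise; without, the referent's drifting arbitrary convention plus
        motor noise.
        """
        if referent not in self.anchors:
            raise ValueError(f"unknown referent {referent!r}")
        p = self.params
        if sees_color:
            a = self.anchors[referent]
            return self._noisy(a.u, a.v, p.sigma_motor, rng)
        conv = self._conventions.get(referent)
        if conv is None or rng.random() < p.p_forget:
            conv = (float(rng.random()), float(rng.random()))
        else:
            cu = conv[0] + p.sigma_drift * rng.standard_normal()
            cv = conv[1] + p.sigma_drift * rng.standard_normal()
            conv = (min(1.0, max(0.0, cu)), min(1.0, max(0.0, cv)))
        self._conventions[referent] = conv
        return self._noisy(conv[0], conv[1], p.sigma_motor, rng)


def _features(view: SignalView) -> Tuple[str, Tuple[float, ...]]:
    if view.kind == "color":
        c = view.payload
        return "color", (c.L, c.a, c.b)
    if view.kind == "dot":
        d = view.payload
        return "dot", (d.u, d.v)
    raise ValueError("cannot extract features from a blank view")


class Receiver:
    """Exemplar-memory receiver with an optional iconic prior for colors."""

    def __init__(self, params: Optional[ReceiverParams] = None) -> None:
        self.params = params or ReceiverParams()
        anchors = _validate_anchors(self.params.anchors or DEFAULT_ANCHORS)
        self._anchor_lab: Dict[str, Tuple[float, float, float]] = {}
        for r, a in anchors.items():
            c = pad_to_lab(a)
            self._anchor_lab[r] = (c.L, c.a, c.b)
        self._exemplars: Dict[str, List[Tuple[str, Tuple[float, ...]]]] = {
            r: [] for r in REFERENTS
        }
        self._pinned: Dict[str, List[Tuple[str, Tuple[float, ...]]]] = {
            r: [] for r in REFERENTS
        }

    def _kernel(self, kind: str, f1: Sequence[float], f2: Sequence[float]) -> float:
        tau = self.params.tau_lab if kind == "color" else self.params.tau_pad
        d2 = sum((a - b) ** 2 for a, b in zip(f1, f2))
        return math.exp(-d2 / (tau * tau))

    def _exemplar_similarity(self, referent: str, kind: str, feat: Sequence[float]) -> float:
        best = 0.0
        for k, f in self._exemplars[referent]:
            if k == kind:
                s = self._kernel(kind, feat, f)
                if s > best:
                    best = s
        for k, f in self._pinned[referent]:
            if k == kind:
                s = self._kernel(kind, feat, f)
                if s > best:
                    best = s
        return best

    def scores(self, view: SignalView) -> Dict[str, float]:
        """Per-referent evidence: (1-λ)·exemplar similarity + λ·iconic prior.

        λ is the configured prior weight for color views and 0 for dot
        views (a dot carries no iconicity the receiver could exploit).
        """
        kind, feat = _features(view)
        lam = self.params.lambda_prior if kind == "color" else 0.0
        out: Dict[str, float] = {}
        for r in REFERENTS:
            s_ex = self._exemplar_similarity(r, kind, feat)
            prior = self._kernel("color", feat, self._anchor_lab[r]) if kind == "color" else 0.0
            out[r] = (1.0 - lam) * s_ex + lam * prior
        return out

    def guess(self, view: SignalView, rng: np.random.Generator) -> str:
        """Guess a referent for ``view``: lapse with probability ε, else
        argmax of :meth:`scores` with uniform tie-breaking."""
        eps = self.params.epsilon_guess
        if eps > 0.0 and rng.random() < eps:
            return REFERENTS[rng.integers(len(REFERENTS))]
        sc = self.scores(view)
        best = max(sc.values())
        ties = [r for r in REFERENTS if sc[r] == best]
        if len(ties) == 1:
            return ties[0]
        return ties[rng.integers(len(ties))]

    def learn(
        self,
        view: SignalView,
        true_referent: str,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        """Store the feedback exemplar, evicting the oldest beyond capacity.

        With an ``rng``, the stored features are perturbed by the encoding
        noise (``sigma_memory_pad``/``sigma_memory_lab``); without one the
        exemplar is stored verbatim.
        """
        if true_referent not in self._exemplars:
            raise ValueError(f"unknown referent {true_referent!r}")
        kind, feat = _features(view)
        if rng is not None:
            sig = self.params.sigma_memory_lab if kind == "color" else self.params.sigma_memory_pad
            if sig > 0.0:
                feat = tuple(x + sig * rng.standard_normal() for x in feat)
        store = self._exemplars[true_referent]
        store.append((kind, feat))
        while len(store) > self.params.memory_capacity:
            store.pop(0)

    def pin(self, view: SignalView, referent: str) -> None:
        """Pin a permanent exemplar (the follow-up experiment's signal log)."""
        if referent not in self._pinned:
            raise ValueError(f"unknown referent {referent!r}")
        self._pinned[referent].append(_features(view))

    def n_exemplars(self, referent: str) -> int:
        return len(self._exemplars[referent])


def generate_cohort(
    n_per_condition: Sequence[int] = (22, 22, 24),
    sender_params: Optional[SenderParams] = None,
    receiver_params: Optional[ReceiverParams] = None,
    config: Optional[GameConfig] = None,
    seed: int = 0,
) -> List[GameLog]:
    """Simulate a cohort of dyads across the three conditions.

    ``n_per_condition`` gives dyad counts for (high, low, one_sided); the
    default mirrors the study design of 22/22/24 dyads.  Each dyad gets
    fresh agents and an independent child seed of the master seed, so the
    whole cohort is reproducible bit for bit.  ``config`` supplies session
    parameters; its ``condition`` field is overridden per dyad.
    """
    if any(n < 1 for n in n_per_condition) or len(n_per_condition) != 3:
        raise ValueError("n_per_condition must give three counts >= 1")
    base = config or GameConfig(condition="high")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(int(sum(n_per_condition))))
    logs: List[GameLog] = []
    for cond, n in zip(CONDITIONS, n_per_condition):
        cfg = replace(base, condition=cond)
        for i in range(n):
            log = run_game(
                cfg,
                Sender(sender_params),
                Receiver(receiver_params),
                next(children),
                dyad_id=f"{cond}_{i:02d}",
            )
            logs.append(log)
    return logs


def make_signal_bank(
    seed: int = 0,
    sender_params: Optional[SenderParams] = None,
    receiver_params: Optional[ReceiverParams] = None,
) -> Dict[str, List[PadPoint]]:
    """Build the follow-up experiment's 18-signal bank from one simulated
    high-iconicity game: the first three sent points per referent.

    Three signals per referent preserve the production noise a human
    receiver would have faced.
    """
    log = run_game(
        GameConfig(condition="high"),
        Sender(sender_params),
        Receiver(receiver_params),
        np.random.SeedSequence(seed),
        dyad_id="bank_source",
    )
    bank: Dict[str, List[PadPoint]] = {r: [] for r in REFERENTS}
    for rec in log.rounds:
        if rec.sent_point is not None and len(bank[rec.target]) < 3:
            bank[rec.target].append(rec.sent_point)
    if any(len(v) < 3 for v in bank.values()):
        raise RuntimeError("source game too short to fill the signal bank")
    return bank


def estimate_sigma_motor(distances: Iterable[float]) -> float:
    """Method-of-moments motor-noise estimate from stability distances.

    Successive productions of an anchored referent are iid
    ``N(anchor, σ² I₂)``, so their difference is ``N(0, 2σ² I₂)`` and the
    distance is Rayleigh with scale ``σ√2``, giving ``E d = σ√π``.  Hence
    ``σ̂ = mean(d) / √π``.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("need at least one stability distance")
    return float(d.mean() / math.sqrt(math.pi))
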