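"""The active-learning loop: episode scheduling, selection, retraining, termination.

One AL iteration trains the MLP on the current set, propagates an MLP-MD
episode of (n³ + 2) fs (n is the index of the MD run, starting at 0, reset
to 0 after every accepted structure) and hands the episode's last frame to
the selector. Accepted frames are labeled with the reference backend and
appended; the run is converged when no structure is selected within the
maximum simulation time (episode durations follow 2, 3, 10, 29, … fs until
the next episode would exceed the cap, 5 ps by default).

The four-subset training strategy for solvated reactions (solute alone,
solute + a few solvent molecules, solute + solvent cluster, pure solvent)
is orchestrated by :func:`build_subsets` / :func:`run_subsets`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .core import Configuration, ConfigurationSet, random_displace
from .descriptors import SoapCalculator, SoapParams
from .dynamics import MDParams, run_md
from .potentials import Potential, SoapKrrMlp
from .selectors import (
    DistanceSelectorConfig,
    EnergySelectorConfig,
    SimilaritySelectorConfig,
    distance_select,
    energy_select,
    similarity_select,
)


def md_schedule(n: int) -> float:
    """Episode duration in fs for MD-run index n: (n³ + 2) fs."""
    if n < 0:
        raise ValueError("MD-run index must be non-negative")
    return float(n**3 + 2)


@dataclass
class ALConfig:
    """Settings of one active-learning job."""

    selector: str = "similarity"           # energy | similarity | distance
    selector_config: object | None = None  # defaulted per selector type
    soap: SoapParams = field(default_factory=SoapParams)
    mlp_soap: object | None = None         # SoapParams or tuple of them; defaults to soap
    max_time: float = 5000.0               # fs; episode cap triggering convergence
    max_al_iterations: int = 500
    temperature: float = 300.0             # K, MD episodes
    dt: float = 0.5                        # fs
    ensemble: str = "NVT"
    friction: float = 0.02                 # fs⁻¹
    lam: float = 1e-11                     # ridge, relative to the design-matrix scale
    zeta: int = 4                          # kernel exponent (MLP and similarity selector)
    rng_seed: int = 0
    restart: str = "initial"               # episode start: initial | latest-accepted

    def __post_init__(self):
        if self.restart not in ("initial", "latest"):
            raise ValueError("restart must be 'initial' or 'latest'")
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")
        defaults = {
            "energy": EnergySelectorConfig,
            "similarity": lambda: SimilaritySelectorConfig(zeta=self.zeta),
            "distance": DistanceSelectorConfig,
        }
        if self.selector not in defaults:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.selector_config is None:
            self.selector_config = defaults[self.selector]()
        expected = {
            "energy": EnergySelectorConfig,
            "similarity": SimilaritySelectorConfig,
            "distance": DistanceSelectorConfig,
        }[self.selector]
        if not isinstance(self.selector_config, expected):
            raise TypeError(
                f"selector {self.selector!r} requires {expected.__name__}, "
                f"got {type(self.selector_config).__name__}"
            )


@dataclass
class ALState:
    """Mutable state of a running AL job."""

    n: int = 0                                  # current MD-episode index
    training_set: ConfigurationSet = field(default_factory=ConfigurationSet)
    model: SoapKrrMlp | None = None
    decisions: list = field(default_factory=list)
    converged: bool = False
    reference_calls: int = 0
    iterations: int = 0


@dataclass
class ALResult:
    model: SoapKrrMlp
    training_set: ConfigurationSet
    decisions: list
    converged: bool
    reference_calls: int
    iterations: int

    def write_decision_log(self, path) -> None:
        """JSON-lines log: one selector decision per line."""
        with open(path, "w") as fh:
            for rec in self.decisions:
                fh.write(json.dumps(rec) + "\n")


def _episode_seed(base_seed: int, iteration: int, retry: int = 0) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(iteration, retry))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def al_train(
    initial_set: ConfigurationSet,
    reference: Potential,
    cfg: ALConfig,
    start_config: Configuration | None = None,
) -> ALResult:
    """Run the AL loop and return the converged model with its training set.

    ``initial_set`` members lacking labels are labeled with the reference
    backend first. Each episode starts from the designated start structure
    of the initial set with fresh Maxwell-Boltzmann velocities (set
    ``cfg.restart="latest"`` to continue from the most recently accepted
    structure instead — faster exploration, but an unstable early model can
    then drag the run into ever more distorted regions).
    The energy selector calls the reference on every evaluated frame; the
    descriptor selectors only on accepted frames — this cost asymmetry is
    visible in ``reference_calls``.
    """
    if len(initial_set) == 0:
        raise ValueError("initial training set is empty")
    state = ALState()
    calc = SoapCalculator.get(cfg.soap)

    for config in initial_set:
        if config.energy is None or config.label_source != reference.label:
            config = reference.label_config(config.stripped())
            state.reference_calls += 1
        state.training_set.append(config)
    if cfg.selector == "distance":
        need = cfg.selector_config.min_initial_size
        if len(state.training_set) < need:
            raise ValueError(
                f"distance selector requires at least {need} initial structures, "
                f"got {len(state.training_set)} — it relies on neighbour information"
            )

    descriptors = [calc.descriptor(c)[0] for c in state.training_set]
    model = SoapKrrMlp(cfg.mlp_soap or cfg.soap, lam=cfg.lam, zeta=cfg.zeta)
    model.ensure_sparse(state.training_set)
    from .potentials import _NormalEquations

    neq = _NormalEquations(model.n_design_features)  # running design accumulation
    for c in state.training_set:
        model.add_rows(neq, model.rows_for(c))

    def retrain():
        state.model = model.fit_neq(neq)

    retrain()
    start = start_config if start_config is not None else initial_set[0]
    start = start.copy()

    while state.iterations < cfg.max_al_iterations:
        duration = md_schedule(state.n)
        if duration > cfg.max_time:
            state.converged = True
            break
        candidate = None
        unstable = False
        for retry in range(3):
            md = MDParams(
                dt=cfg.dt, temperature=cfg.temperature, ensemble=cfg.ensemble,
                friction=cfg.friction, duration=duration,
                rng_seed=_episode_seed(cfg.rng_seed, state.iterations, retry),
                stride=10**9,
            )
            traj = run_md(start, state.model, md)
            final = traj.final
            if np.all(np.isfinite(final.positions)):
                candidate = final
                unstable = traj.unstable
                break
            state.decisions.append(
                {"iteration": state.iterations, "n": state.n, "event": "nonfinite_retry",
                 "retry": retry}
            )
        if candidate is None:
            raise RuntimeError(
                "MD episode produced non-finite coordinates in three attempts — "
                "the model is too poor to propagate; enlarge the initial set"
            )

        candidate = candidate.stripped()
        p_new, _ = calc.descriptor(candidate)
        if cfg.selector == "energy":
            e_ref, f_ref = reference.evaluate(candidate)
            state.reference_calls += 1
            e_mlp = state.model.predict_energy(candidate)
            decision = energy_select(e_ref, e_mlp, cfg.selector_config)
        elif cfg.selector == "similarity":
            decision = similarity_select(p_new, descriptors, cfg.selector_config)
        else:
            decision = distance_select(p_new, descriptors, cfg.selector_config)

        rec = decision.as_record()
        rec.update(
            iteration=state.iterations, n=state.n, duration_fs=duration,
            unstable=bool(unstable), config_id=len(state.training_set),
        )
        state.decisions.append(rec)
        state.iterations += 1

        if decision.verdict == "add":
            if cfg.selector == "energy":
                labeled = candidate.with_labels(e_ref, f_ref, source=reference.label)
            else:
                try:
                    labeled = reference.label_config(candidate)
                except Exception as err:
                    # the reference backend can fail on unphysical structures
                    # (the SCF-non-convergence analogue); drop the frame
                    state.decisions[-1]["event"] = f"reference_failure: {err}"
                    state.n += 1
                    continue
                state.reference_calls += 1
            labeled.provenance = dict(
                labeled.provenance, selector=cfg.selector, al_iteration=state.iterations,
            )
            state.training_set.append(labeled, note=f"iteration {state.iterations}")
            descriptors.append(p_new)
            model.add_rows(neq, model.rows_for(labeled))
            retrain()
            state.n = 0
            if cfg.restart == "latest":
                start = labeled
        else:
            # discarded frames are dropped entirely; both cases advance n
            state.n += 1

    return ALResult(
        model=state.model,
        training_set=state.training_set,
        decisions=state.decisions,
        converged=state.converged,
        reference_calls=state.reference_calls,
        iterations=state.iterations,
    )


# ---------------------------------------------------------------------------
# four-subset training strategy
# ---------------------------------------------------------------------------

@dataclass
class SubsetSpec:
    """One independent AL job in the multi-subset training strategy."""

    name: str
    start_config: Configuration
    n_initial: int = 10
    max_disp: float = 0.1  # Å, random-displacement amplitude for initial data

    def __post_init__(self):
        if self.start_config is None:
            raise ValueError(f"subset {self.name!r} has no start structure")


def build_subsets(
    subsets: list[SubsetSpec], base_config: ALConfig
) -> list[tuple[str, ConfigurationSet, ALConfig]]:
    """Materialize independent AL jobs (name, initial set, config) per subset.

    Each subset's initial data is generated by random displacement of its
    start structure; the jobs run independently and their accepted
    structures are concatenated (deduplicated) before a final full retrain.
    """
    jobs = []
    for i, spec in enumerate(subsets):
        initial = random_displace(
            spec.start_config, spec.max_disp, spec.n_initial,
            rng_seed=_episode_seed(base_config.rng_seed, 1000 + i),
        )
        for c in initial:
            c.provenance["subset"] = spec.name
        cfg = replace(base_config, rng_seed=_episode_seed(base_config.rng_seed, 2000 + i))
        jobs.append((spec.name, initial, cfg))
    return jobs


def deduplicate_by_descriptor(
    configs: ConfigurationSet, soap: SoapParams, tol: float = 1e-12
) -> ConfigurationSet:
    """Drop configurations whose descriptors duplicate an earlier member."""
    calc = SoapCalculator.get(soap)
    kept = ConfigurationSet(name=configs.name)
    X: list[np.ndarray] = []
    for config in configs:
        p, _ = calc.descriptor(config)
        if X and np.max(np.stack(X) @ p) > 1.0 - tol:
            continue
        X.append(p)
        kept.append(config)
    return kept


def run_subsets(
    subsets: list[SubsetSpec],
    reference: Potential,
    base_config: ALConfig,
) -> tuple[SoapKrrMlp, ConfigurationSet, dict]:
    """Run every subset job, combine the training sets, retrain once on the union."""
    jobs = build_subsets(subsets, base_config)
    combined = ConfigurationSet(name="combined")
    logs = {}
    for name, initial, cfg in jobs:
        result = al_train(initial, reference, cfg, start_config=initial[0])
        for config in result.training_set:
            config.provenance.setdefault("subset", name)
        combined.extend(result.training_set, note=f"subset {name}")
        logs[name] = result.decisions
    combined = deduplicate_by_descriptor(combined, base_config.soap)
    model = SoapKrrMlp(base_config.soap, lam=base_config.lam, zeta=base_config.zeta)
    model.fit(combined)
    return model, combined, logs
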