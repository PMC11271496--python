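"""Canonical desk-scale study configurations.

These functions pin down the study conditions used by the validation
scripts and the acceptance suite: the 27-molecule water cluster with the
analytic water reference standing in for the electronic-structure method,
the descriptor channels of its MLP, and the selector operating points.
"""

from __future__ import annotations

import numpy as np

from .active_learning import ALConfig
from .core import Configuration, ConfigurationSet
from .descriptors import SoapParams
from .dynamics import MDParams, run_md
from .potentials import ToyWaterPotential
from .selectors import EnergySelectorConfig, SimilaritySelectorConfig
from .systems import equilibrated_water_cluster


def water_selector_soap() -> SoapParams:
    """Descriptor used by the similarity/distance selectors on water."""
    return SoapParams(r_cut=6.0, sigma_atom=0.25, n_max=9,
                      radial_power=1.3, radial_width_factor=0.8)


def water_mlp_soap() -> SoapParams:
    """Descriptor of the water MLP: same single channel as the selector.

    The descriptor cutoff matches the reference potential's 6 Å interaction
    range (interactions the descriptor cannot see cannot be learned) and
    the power-spaced radial basis concentrates resolution at bonding
    distances.
    """
    return water_selector_soap()


# similarity threshold: thermal frames of the 27-water cluster score
# max(K) ≈ 0.997-0.99995 against a covering training set, so 0.9995 stops
# collecting once the thermally accessible region is represented (a few
# dozen structures — the scale similarity selectors typically end at)
WATER_SIMILARITY_KT = 0.9995
# energy-selector threshold: 0.05 eV ≈ 1.2 kcal/mol on the total energy
WATER_ENERGY_ET = 0.05


def calibrated_similarity_kt(
    initial_set, soap: SoapParams, zeta: int = 4, percentile: float = 20.0,
) -> float:
    """Similarity threshold from the initial data itself.

    The operating point of the similarity selector depends on the system
    (atom-averaged descriptors of small clusters spread much more than
    those of large ones). A robust a-priori rule: accept candidates less
    similar to the training set than the ``percentile``-th percentile of
    the pairwise kernel similarities already present in the initial data —
    "add what is more novel than the existing spread".
    """
    from .descriptors import SoapCalculator

    calc = SoapCalculator.get(soap)
    X = np.stack([calc.descriptor(c)[0] for c in initial_set])
    K = np.abs(X @ X.T) ** zeta
    off_diag = K[np.triu_indices_from(K, k=1)]
    return float(np.percentile(off_diag, percentile))


def water_al_config(selector: str, rng_seed: int, max_time: float = 500.0,
                    max_al_iterations: int = 300) -> ALConfig:
    selector_config = {
        "similarity": lambda: SimilaritySelectorConfig(k_T=WATER_SIMILARITY_KT, zeta=4),
        "energy": lambda: EnergySelectorConfig(E_T=WATER_ENERGY_ET),
        "distance": lambda: None,
    }[selector]()
    return ALConfig(
        selector=selector,
        selector_config=selector_config,
        soap=water_selector_soap(),
        mlp_soap=water_mlp_soap(),
        max_time=max_time,
        max_al_iterations=max_al_iterations,
        temperature=300.0,
        lam=1e-12,
        rng_seed=rng_seed,
    )


def water_study_system(n_molecules: int = 27, rng_seed: int = 0):
    """(reference potential, equilibrated cluster) for the selector study."""
    reference = ToyWaterPotential()
    cluster = equilibrated_water_cluster(
        n_molecules, reference, rng_seed=rng_seed, equilibration_fs=1000.0,
    )
    return reference, cluster


def reference_snapshots(
    reference, start: Configuration, n_frames: int, rng_seed: int,
    interval_fs: float = 50.0, labeled: bool = True,
) -> ConfigurationSet:
    """Reference-MD snapshots from a common start structure.

    Used both for the initial AL data of the condensed-phase system and for
    held-out evaluation frames (with different seeds).
    """
    stride = max(1, int(round(interval_fs / 0.5)))
    params = MDParams(dt=0.5, temperature=300.0, ensemble="NVT",
                      duration=n_frames * interval_fs, rng_seed=rng_seed,
                      stride=stride)
    traj = run_md(start, reference, params)
    if traj.unstable:
        raise RuntimeError("reference sampling became unstable")
    frames = traj.frames[1 : n_frames + 1]
    out = ConfigurationSet(name="reference_snapshots")
    for i, f in enumerate(frames):
        c = reference.label_config(f.stripped()) if labeled else f.stripped()
        c.provenance = {"origin": "initial", "index": i}
        out.append(c)
    return out
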