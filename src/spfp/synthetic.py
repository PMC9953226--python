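"""Synthetic activity classes with a known structure->potency map.

Real activity classes are proprietary-database extracts; this module
generates stand-ins whose statistics emulate them closely enough to
exercise every model end to end: sparse 2048-bit binary fingerprints
drawn from a small number of cluster profiles (mimicking analog
series), and potencies that are a noisy linear function of a subset of
"signal" bits, unimodal over pIC50 5-11 with the median near the
high-nanomolar range. Because the generative map is known exactly, the
generated classes double as ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curation import ActivityClass, CompoundRecord

__all__ = ["SyntheticClassSpec", "generate_activity_class", "generate", "smiles_fixtures"]


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Parameters of the generative model.

    Defaults produce a class resembling a typical benchmark set: ~10
    analog-series clusters of sparse fingerprints, potency centered at
    pIC50 7 (high-nanomolar) with an overall spread close to one log
    unit, of which ``noise_sd`` log units are structure-independent.
    """

    n_compounds: int = 1000
    n_bits: int = 2048
    n_clusters: int = 10
    n_signal_bits: int = 40
    effect_size: float = 0.3
    noise_sd: float = 0.4
    potency_center: float = 7.0
    seed: int = 0
    target_id: str = "SYN"

    def __post_init__(self) -> None:
        if self.n_signal_bits > self.n_bits:
            raise ValueError("n_signal_bits cannot exceed n_bits")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_compounds < 1 or self.n_clusters < 1:
            raise ValueError("n_compounds and n_clusters must be positive")


def generate(spec: SyntheticClassSpec) -> tuple[ActivityClass, dict]:
    """Generate an activity class plus the generative truth.

    The returned dict records everything needed to evaluate the exact
    generative map on any fingerprint: signal bit indices, effect size,
    the centering constant, and the potency center.

    Mechanics: three child RNG streams (profiles, compounds, noise) are
    spawned from the single seed so each stage is independently
    reproducible. Per-cluster background bit probabilities come from
    Beta(0.2, 2) (sparse, ECFP-like); signal-bit probabilities are set
    to either 0.1 or 0.8 per cluster, giving the across-cluster
    contrast that makes potency learnable from structure. Potency is
    ``center + effect_size * (s_i - mean(s)) + N(0, noise_sd^2)``
    clipped to [5, 11], where s_i counts the set signal bits.
    """
    rng_profiles, rng_compounds, rng_noise = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(3)
    )

    # cluster profiles: background sparse, signal bits high-contrast
    profiles = rng_profiles.beta(0.2, 2.0, size=(spec.n_clusters, spec.n_bits))
    signal_idx = rng_profiles.choice(spec.n_bits, size=spec.n_signal_bits, replace=False)
    if spec.n_signal_bits:
        contrast = rng_profiles.choice(
            [0.1, 0.8], size=(spec.n_clusters, spec.n_signal_bits)
        )
        profiles[:, signal_idx] = contrast

    assignment = rng_compounds.integers(spec.n_clusters, size=spec.n_compounds)
    fps = (
        rng_compounds.random((spec.n_compounds, spec.n_bits)) < profiles[assignment]
    ).astype(np.uint8)

    s = fps[:, signal_idx].sum(axis=1).astype(float) if spec.n_signal_bits else np.zeros(
        spec.n_compounds
    )
    s_center = float(s.mean())
    noise = rng_noise.normal(0.0, spec.noise_sd, size=spec.n_compounds) if spec.noise_sd else 0.0
    potency = np.clip(
        spec.potency_center + spec.effect_size * (s - s_center) + noise, 5.0, 11.0
    )

    records = [
        CompoundRecord(
            compound_id=f"{spec.target_id}-{i:05d}",
            smiles=None,
            pIC50=float(potency[i]),
            target_id=spec.target_id,
            fingerprint=fps[i],
        )
        for i in range(spec.n_compounds)
    ]
    truth = {
        "signal_idx": signal_idx,
        "effect_size": spec.effect_size,
        "s_center": s_center,
        "potency_center": spec.potency_center,
        "cluster_assignment": assignment,
    }
    return ActivityClass(spec.target_id, records), truth


def generate_activity_class(spec: SyntheticClassSpec) -> ActivityClass:
    """Generate an activity class (see :func:`generate`)."""
    return generate(spec)[0]


# Hand-picked drug-like molecules (all MW < 1000, PAINS-clean) with
# plausible but invented pIC50 values, for end-to-end SMILES tests.
_FIXTURES: list[tuple[str, str, float]] = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O", 5.3),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", 5.8),
    ("naproxen", "COc1ccc2cc(ccc2c1)C(C)C(=O)O", 6.1),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1", 5.1),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", 5.2),
    ("celecoxib", "Cc1ccc(cc1)-c1cc(nn1-c1ccc(cc1)S(N)(=O)=O)C(F)(F)F", 7.4),
    ("diazepam", "CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1", 7.9),
    ("propranolol", "CC(C)NCC(O)COc1cccc2ccccc12", 8.2),
    ("atenolol", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1", 6.6),
    ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O", 6.9),
    ("lidocaine", "CCN(CC)CC(=O)Nc1c(C)cccc1C", 5.9),
    ("metoprolol", "COCCc1ccc(OCC(O)CNC(C)C)cc1", 6.8),
    ("imatinib_core", "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1", 8.7),
    ("sildenafil", "CCCc1nn(C)c2c1nc(-c1cc(S(=O)(=O)N3CCN(C)CC3)ccc1OCC)[nH]c2=O", 8.9),
    ("chlorpromazine", "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21", 7.6),
    ("fluoxetine", "CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1", 7.1),
    ("amoxicillin_core", "CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O", 5.6),
    ("haloperidol", "OC1(CCN(CCCC(=O)c2ccc(F)cc2)CC1)c1ccc(Cl)cc1", 8.4),
    ("verapamil", "COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC", 6.4),
    ("loratadine", "CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1", 7.7),
    ("sulfamethoxazole", "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1", 5.4),
    ("gefitinib_core", "COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1", 8.1),
]


def smiles_fixtures() -> list[CompoundRecord]:
    """Small hand-written set of valid drug-like SMILES with pIC50.

    All fixtures parse, have MW < 1000 Da, pIC50 in [5, 11], and pass
    the default curation filters (including the PAINS screen); potency
    values are invented for testing, not measurements.
    """
    return [
        CompoundRecord(compound_id=name, smiles=smi, pIC50=p, target_id="FIX")
        for name, smi, p in _FIXTURES
    ]
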