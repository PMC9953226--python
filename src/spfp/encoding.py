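"""Structure-potency fingerprint (SPFP) codec.

An SPFP concatenates two bit modules into one fixed-format bit string:

* a **structure module** — a 2048-bit folded extended-connectivity
  fingerprint (ECFP4, Morgan radius 2) of the compound, and
* a **potency module** — a cumulative ("thermometer") encoding of the
  compound's pIC50 over the range 5-11, in which a potency falling into
  the k-th resolution interval sets bits 0..k, so more potent compounds
  are bit-supersets of less potent ones.

At the default 100-bit potency module each bit spans 0.06 log units, so
decoding a module to the center of its interval carries a constant
half-width of 0.03 log units.

Layout convention: bit 0 of the potency module is the lowest-potency
interval; the SPFP vector is ``[structure | potency]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "PotencyModuleSpec",
    "PotencyRangeError",
    "InvalidModuleError",
    "SmilesParseError",
    "DEFAULT_SPEC",
    "STRUCTURE_BITS",
    "bit_resolution",
    "encode_potency",
    "decode_potency",
    "is_valid_module",
    "structure_fingerprint",
    "build_spfp",
    "SPFP",
]

#: Length of the structure module (folded ECFP4).
STRUCTURE_BITS = 2048

#: Guard added before flooring the interval index; absorbs binary
#: representation error of decimal resolutions such as 0.06 so that a
#: value sitting exactly on an interior interval boundary lands in the
#: higher interval (8.0 -> interval 50 -> 51 set bits).
_INDEX_EPS = 1e-9


class PotencyRangeError(ValueError):
    """pIC50 value outside the range covered by the potency module."""


class InvalidModuleError(ValueError):
    """Bit pattern is not a non-empty contiguous prefix run of ones."""


class SmilesParseError(ValueError):
    """SMILES string could not be parsed into a molecule."""


@dataclass(frozen=True)
class PotencyModuleSpec:
    """Geometry of the cumulative potency module.

    Parameters
    ----------
    n_bits
        Number of bit positions L (default 100).
    range_low, range_high
        pIC50 range covered, default [5, 11].
    """

    n_bits: int = 100
    range_low: float = 5.0
    range_high: float = 11.0

    def __post_init__(self) -> None:
        if self.n_bits < 1:
            raise ValueError(f"n_bits must be >= 1, got {self.n_bits}")
        if not self.range_high > self.range_low:
            raise ValueError(
                f"range_high ({self.range_high}) must exceed range_low ({self.range_low})"
            )

    @property
    def resolution(self) -> float:
        """Log units represented by one bit position."""
        return (self.range_high - self.range_low) / self.n_bits

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_bits": self.n_bits,
                "range_low": self.range_low,
                "range_high": self.range_high,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "PotencyModuleSpec":
        return cls(**json.loads(payload))


DEFAULT_SPEC = PotencyModuleSpec()


def bit_resolution(spec: PotencyModuleSpec = DEFAULT_SPEC) -> float:
    """Log units of potency represented by a single bit of the module."""
    return spec.resolution


def _interval_index(p: float, spec: PotencyModuleSpec) -> int:
    """Index of the half-open interval [low + k*r, low + (k+1)*r) holding p.

    The top of the range is clamped into the last interval so that
    p = range_high is representable.
    """
    k = int(np.floor((p - spec.range_low) / spec.resolution + _INDEX_EPS))
    return min(max(k, 0), spec.n_bits - 1)


def encode_potency(p: float, spec: PotencyModuleSpec = DEFAULT_SPEC) -> np.ndarray:
    """Cumulatively encode a pIC50 value into a potency module.

    The value's interval index k determines the bit pattern: positions
    0..k are set (k+1 bits), the rest are zero.

    Raises
    ------
    PotencyRangeError
        If ``p`` lies outside ``[spec.range_low, spec.range_high]``.
    """
    if not np.isfinite(p) or p < spec.range_low or p > spec.range_high:
        raise PotencyRangeError(
            f"pIC50 {p} outside supported range [{spec.range_low}, {spec.range_high}]"
        )
    k = _interval_index(float(p), spec)
    bits = np.zeros(spec.n_bits, dtype=np.uint8)
    bits[: k + 1] = 1
    return bits


def is_valid_module(bits: np.ndarray, spec: PotencyModuleSpec = DEFAULT_SPEC) -> bool:
    """Check the cumulative-encoding validity criterion.

    A module is valid iff at least one bit is set and the set bits form a
    single contiguous run starting at position 0 (a non-empty prefix of
    ones). Sampled modules violating this cannot be interpreted as a
    potency and are rejected during prediction.
    """
    bits = np.asarray(bits)
    if bits.shape != (spec.n_bits,):
        raise ValueError(
            f"expected bit vector of shape ({spec.n_bits},), got {bits.shape}"
        )
    n_set = int(np.count_nonzero(bits))
    if n_set == 0:
        return False
    return bool(np.all(bits[:n_set] != 0) and np.all(bits[n_set:] == 0))


def decode_potency(bits: np.ndarray, spec: PotencyModuleSpec = DEFAULT_SPEC) -> float:
    """Decode a valid potency module to the center of its interval.

    A module with k+1 set bits maps to ``range_low + k*r + r/2``; every
    decoded value therefore carries a constant half-width of r/2
    (0.03 log units at the default spec).

    Raises
    ------
    InvalidModuleError
        If the pattern is not a non-empty contiguous prefix of ones.
    """
    if not is_valid_module(bits, spec):
        raise InvalidModuleError(
            "potency module is not a non-empty contiguous prefix of set bits"
        )
    k = int(np.count_nonzero(bits)) - 1
    r = spec.resolution
    return spec.range_low + k * r + r / 2.0


_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=STRUCTURE_BITS)


def structure_fingerprint(smiles: str) -> np.ndarray:
    """2048-bit binary ECFP4 (Morgan, radius 2, folded) of a SMILES string.

    Deterministic across different SMILES notations of the same molecule
    (the toolkit canonicalizes atom environments, not atom order).

    Raises
    ------
    SmilesParseError
        If the SMILES cannot be parsed.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    fp = _MORGAN_GEN.GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


@dataclass(frozen=True)
class SPFP:
    """A structure-potency fingerprint: ``[structure | potency]``.

    The two modules stay independently addressable: the structure module
    is the condition vector of the CVAE, the potency module its
    reconstruction target.
    """

    structure: np.ndarray
    potency: np.ndarray
    spec: PotencyModuleSpec = field(default=DEFAULT_SPEC)

    def __post_init__(self) -> None:
        if self.structure.shape != (STRUCTURE_BITS,):
            raise ValueError(
                f"structure module must have {STRUCTURE_BITS} bits, got {self.structure.shape}"
            )
        if self.potency.shape != (self.spec.n_bits,):
            raise ValueError(
                f"potency module must have {self.spec.n_bits} bits, got {self.potency.shape}"
            )

    @property
    def bits(self) -> np.ndarray:
        """Full concatenated bit string of length 2048 + L."""
        return np.concatenate([self.structure, self.potency])

    def __len__(self) -> int:
        return STRUCTURE_BITS + self.spec.n_bits

    def decode(self) -> float:
        """pIC50 encoded in the potency module (interval center)."""
        return decode_potency(self.potency, self.spec)

    def to_hex(self) -> str:
        """Serialize the full bit string as a hex string (MSB-first)."""
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, payload: str, spec: PotencyModuleSpec = DEFAULT_SPEC) -> "SPFP":
        total = STRUCTURE_BITS + spec.n_bits
        raw = np.frombuffer(bytes.fromhex(payload), dtype=np.uint8)
        bits = np.unpackbits(raw)[:total].astype(np.uint8)
        return cls(bits[:STRUCTURE_BITS], bits[STRUCTURE_BITS:], spec)


def build_spfp(
    structure: np.ndarray, p: float, spec: PotencyModuleSpec = DEFAULT_SPEC
) -> SPFP:
    """Assemble an SPFP from a structure module and a pIC50 value."""
    structure = np.asarray(structure, dtype=np.uint8)
    return SPFP(structure, encode_potency(p, spec), spec)
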