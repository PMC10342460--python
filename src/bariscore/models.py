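"""Inheritance-model encodings of genotype dosage.

All encodings are defined relative to the reference-allele homozygote:
dominant = carrier of any alternate allele, recessive = alternate homozygote,
over-dominant = heterozygote, log-additive = alternate-allele count, and
codominant = separate indicators for heterozygote and alternate homozygote.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .errors import AlleleMismatchError
from .genotypes import MISSING, call_to_dosage


class InheritanceModel(str, Enum):
    CODOMINANT = "codominant"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    OVERDOMINANT = "overdominant"
    LOG_ADDITIVE = "log_additive"

    @property
    def n_genetic_params(self) -> int:
        return 2 if self is InheritanceModel.CODOMINANT else 1


#: AIC tie-break order after the fewer-genetic-parameters rule.
TIE_BREAK_ORDER = (
    InheritanceModel.LOG_ADDITIVE,
    InheritanceModel.DOMINANT,
    InheritanceModel.RECESSIVE,
    InheritanceModel.OVERDOMINANT,
    InheritanceModel.CODOMINANT,
)

ALL_MODELS = tuple(InheritanceModel)


def encode_inheritance(dosage: np.ndarray, model: InheritanceModel) -> np.ndarray:
    """Encode alt-allele dosage under an inheritance model.

    Parameters
    ----------
    dosage
        Integer array with values in ``{-1, 0, 1, 2}``; ``-1`` means missing.
    model
        The inheritance model to encode.

    Returns
    -------
    ndarray of shape ``(n, p)`` with ``p = 1`` (``p = 2`` for codominant);
    missing calls propagate as NaN.
    """
    d = np.asarray(dosage)
    miss = d == MISSING
    model = InheritanceModel(model)
    if model is InheritanceModel.DOMINANT:
        cols = [(d >= 1).astype(float)]
    elif model is InheritanceModel.RECESSIVE:
        cols = [(d == 2).astype(float)]
    elif model is InheritanceModel.OVERDOMINANT:
        cols = [(d == 1).astype(float)]
    elif model is InheritanceModel.LOG_ADDITIVE:
        cols = [d.astype(float)]
    else:  # codominant
        cols = [(d == 1).astype(float), (d == 2).astype(float)]
    out = np.column_stack(cols)
    out[miss, :] = np.nan
    return out


def encode_calls(
    calls: list[str], ref: str, alt: str, model: InheritanceModel
) -> np.ndarray:
    """Encode string genotype calls (``"X/Y"`` / ``"./."``) directly.

    Raises :class:`AlleleMismatchError` if any call carries an allele letter
    outside the ``ref``/``alt`` pair.
    """
    bad: list[str] = []
    dosage = np.empty(len(calls), dtype=np.int8)
    for i, c in enumerate(calls):
        try:
            dosage[i] = call_to_dosage(c, ref, alt)
        except AlleleMismatchError as err:
            bad.extend(err.records or [c])
            dosage[i] = MISSING
    if bad:
        raise AlleleMismatchError(
            f"{len(bad)} call(s) with alleles outside {ref}/{alt}: {bad[:5]}", records=bad
        )
    return encode_inheritance(dosage, model)
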