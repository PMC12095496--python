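"""Minimum-free-energy folding of spacers (RNA) and donors (DNA).

Wraps the ViennaRNA python bindings. ΔG is the unimolecular MFE at 37 °C,
in kcal/mol; a positive MFE (no stable structure) is reported as 0, so all
returned values are ≤ 0. The spacer uses RNA nearest-neighbour parameters
(Turner 2004); single-stranded DNA donors use DNA parameters
(Mathews 2004). ViennaRNA's energy parameter tables are process-global, so
the DNA path saves and restores the RNA tables around each call.
"""

from __future__ import annotations

from .guides import normalize_sequence, validate_spacer

try:
    import RNA as _vienna
except ImportError:  # pragma: no cover - environment without bindings
    _vienna = None


class FoldingBackendError(RuntimeError):
    pass


def _require_backend():
    if _vienna is None:
        raise FoldingBackendError(
            "ViennaRNA python bindings are not available; supply precomputed "
            "free-energy columns (delta_g) in the feature table instead"
        )
    return _vienna


def _mfe(sequence: str) -> float:
    backend = _require_backend()
    fc = backend.fold_compound(sequence)
    _, mfe = fc.mfe()
    return float(mfe)


def spacer_free_energy(spacer: str) -> float:
    """MFE (kcal/mol, ≤ 0) of the 20-nt spacer folded as RNA at 37 °C.

    Accepts DNA or RNA spelling; the 20-mer is folded as RNA since the
    physical species is the gRNA spacer.
    """
    s = validate_spacer(spacer)
    rna = s.replace("T", "U")
    return min(_mfe(rna), 0.0)


def donor_free_energy(sequence: str) -> float:
    """MFE (kcal/mol, ≤ 0) of a single-stranded DNA donor at 37 °C.

    Folded as written in its delivered orientation with DNA (Mathews 2004)
    parameters; reverse-complement donors are therefore folded as their own
    sequence, not re-oriented.
    """
    backend = _require_backend()
    seq = normalize_sequence(sequence)
    if not seq:
        raise ValueError("empty donor sequence")
    backend.params_load_DNA_Mathews2004()
    try:
        dg = _mfe(seq)
    finally:
        backend.params_load_RNA_Turner2004()
    return min(dg, 0.0)


def backend_info() -> dict:
    """Name/version of the folding backend, for provenance in outputs."""
    if _vienna is None:
        return {"backend": None, "version": None}
    return {"backend": "ViennaRNA", "version": getattr(_vienna, "__version__", "?")}
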