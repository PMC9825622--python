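"""Exception hierarchy for chemlm.

Every module raises subclasses of :class:`ChemlmError` so callers can
distinguish pipeline-stage failures from programming errors.
"""


class ChemlmError(Exception):
    """Base class for all chemlm errors."""


# --- chem_io ---------------------------------------------------------------

class UnparseableSmiles(ChemlmError):
    """The input string is not valid SMILES."""


class EmptyAfterStripping(ChemlmError):
    """No organic fragment remains after salt stripping."""


class UnknownToken(ChemlmError):
    """A symbol is absent from the vocabulary."""


# --- neural models ---------------------------------------------------------

class ShapeMismatch(ChemlmError):
    """Token indices or tensors are incompatible with the architecture."""


class VocabMismatch(ChemlmError):
    """A model was given data tokenized with a different vocabulary."""


class InvalidTemperature(ChemlmError):
    """Sampling temperature must be strictly positive."""


class InvalidNucleus(ChemlmError):
    """Nucleus parameter must lie in [0, 1)."""


# --- ELECTRA ---------------------------------------------------------------

class SingletonVocabulary(ChemlmError):
    """Corruption is impossible: no alternative chemical token exists."""


class InvalidTrainingData(ChemlmError):
    """Training data is degenerate (e.g. no positive corruption labels)."""


# --- ordinal ensemble ------------------------------------------------------

class DegenerateClass(ChemlmError):
    """An activity class required by the operation is empty."""


class TooFewRecords(ChemlmError):
    """Not enough records for the requested number of clusters."""


class DegenerateTestSet(ChemlmError):
    """The test set lacks a class needed to compute the operating point."""


# --- library metrics -------------------------------------------------------

class LengthMismatch(ChemlmError):
    """Fingerprints have different bit lengths."""


class AcyclicMolecule(ChemlmError):
    """The molecule has no ring system, hence no scaffold."""


class DimensionMismatch(ChemlmError):
    """Embedding summaries have incompatible dimensions or featurizers."""


class NonPSDCovariance(ChemlmError):
    """A covariance matrix is not positive semidefinite."""


# --- virtual screen --------------------------------------------------------

class RankVectorMismatch(ChemlmError):
    """Per-query rank vectors do not cover the same library."""


# --- dose response ---------------------------------------------------------

class NonPositiveDose(ChemlmError):
    """Doses must be strictly positive."""


class InsufficientData(ChemlmError):
    """Too few dose points to fit the binding model."""


class FitDiverged(ChemlmError):
    """The nonlinear fit did not converge to an identifiable optimum."""


# --- pipeline --------------------------------------------------------------

class StageError(ChemlmError):
    """A pipeline stage failed; carries the stage name for attribution."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
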