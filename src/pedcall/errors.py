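"""Exception hierarchy.

Pedigree-file problems are ``PedigreeError`` subclasses (they are input
validation failures), likelihood-file problems are ``VariantIOError``
subclasses, and numerical failures inside the engines are
``InferenceError`` subclasses.
"""


class PedcallError(Exception):
    """Base class for all package-specific errors."""


class PedigreeError(PedcallError, ValueError):
    """Invalid pedigree structure file."""


class MissingParentError(PedigreeError):
    """A member lists exactly one parent; pedigrees must be complete."""


class GenderInconsistencyError(PedigreeError):
    """A referenced father is female, or a referenced mother is male."""


class DanglingReferenceError(PedigreeError):
    """A parent id does not correspond to any row in the file."""


class DuplicateIdError(PedigreeError):
    """Duplicate member id or duplicate non-NA sample name."""


class CyclicAncestryError(PedigreeError):
    """A member is its own ancestor."""


class LoopedPedigreeError(PedigreeError):
    """The pedigree contains a loop and the requested method cannot handle it."""


class VariantIOError(PedcallError, ValueError):
    """Invalid likelihood input file."""


class MalformedPLError(VariantIOError):
    """A PL entry has the wrong arity or contains negative values."""


class MissingPLError(VariantIOError):
    """The VCF FORMAT does not define PL."""


class SampleMismatchError(VariantIOError):
    """A sequenced pedigree member is missing from the likelihood file."""


class InferenceError(PedcallError, RuntimeError):
    """Numerical failure inside a posterior engine."""


class NormalizationError(InferenceError):
    """Total joint weight is zero (contradictory evidence at m=0)."""


class SizeCapError(InferenceError):
    """Pedigree too large for exhaustive 3^n enumeration."""


class ZeroConditionalError(InferenceError):
    """A Gibbs full conditional vanished for every genotype."""
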