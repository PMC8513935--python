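"""Exception hierarchy.

``ChemistryError`` groups everything that stems from the input structure
(parsing, unsupported features, atom environments with no registered
parameters); ``NumericError`` covers failures of the free-energy or
fitting machinery.  The CLI maps these onto distinct exit codes.
"""

from __future__ import annotations


class SSIPError(Exception):
    """Base class for all package errors."""


class ChemistryError(SSIPError):
    """A problem with the input chemical structure or its parameterisation."""


class StructureParseError(ChemistryError):
    """The SMILES string could not be parsed."""


class UnsupportedFeatureError(ChemistryError):
    """Parsed fine, but contains features outside the model (charges, isotopes...)."""


class UnassignedAtomError(ChemistryError):
    """An atom environment has no registered group code."""


class UnsupportedRingError(ChemistryError):
    """An aromatic ring substitution pattern has no registered pi-face value."""


class UnknownSolventError(SSIPError, KeyError):
    """Solvent name not in the registry."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message readable
        return self.args[0] if self.args else ""


class UnknownGroupError(SSIPError, KeyError):
    """Group code not in the registry."""

    def __str__(self) -> str:
        return self.args[0] if self.args else ""


class NumericError(SSIPError):
    """Non-finite objective, failed optimisation, or invalid numeric input."""
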