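"""Exception hierarchy.

Errors are grouped into three families so the CLI can map them to distinct
exit codes: configuration errors, file-format errors, and data/domain errors.
"""


class OntosimError(Exception):
    """Base class for all package errors."""


class ConfigError(OntosimError):
    """Invalid run configuration (weights, paths, sampling parameters)."""


class FormatError(OntosimError):
    """Malformed input file (OBO stanza, GAF row, TSV table)."""


class ParseError(FormatError):
    """OBO parse failure; message names the offending stanza."""


class DataError(OntosimError):
    """Valid files, invalid content (unknown terms, empty corpora, ...)."""


class IntegrityError(DataError):
    """Ontology violates structural invariants (e.g. cyclic namespace)."""


class UnknownTermError(DataError, KeyError):
    """Term ID not present (after alt_id resolution) or obsolete."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return Exception.__str__(self)


class NoCommonAncestorError(DataError):
    """Term pair shares no ancestor (different namespaces)."""
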