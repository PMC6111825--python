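"""The published four-subpathway breast-cancer prognostic signature.

Reference data shipped with the package: the four KEGG subpathways (hippo
signalling, long-term depression, PI3K-Akt signalling, purine metabolism),
their member genes, the univariate Cox coefficients of the published
risk-score formula

    risk = 1.013 x a(path:04390_17) + 0.750 x a(path:04730_1)
         + 0.866 x a(path:00230_30) - 0.927 x a(path:04151_102)

and the frozen training-median cutoff 0.1067. Useful for scoring a new
breast-cancer expression cohort without re-deriving a signature, and as a
fixed bookkeeping fixture.
"""

from __future__ import annotations

from .signature import Signature, SignatureMember

__all__ = ["PUBLISHED_CUTOFF", "PUBLISHED_MEMBERS", "published_signature"]

PUBLISHED_CUTOFF = 0.1067

#: (subpathway id, pathway name, Cox coefficient, member genes) in the order
#: the coefficients appear in the published risk-score formula.
PUBLISHED_MEMBERS: tuple[tuple[str, str, float, tuple[str, ...]], ...] = (
    (
        "path:04390_17", "Hippo signalling pathway", 1.013,
        ("YWHAZ", "YWHAG", "YAP1", "SOX2", "SERPINE1", "TEAD3", "BIRC5",
         "FGF1"),
    ),
    (
        "path:04730_1", "Long-term depression", 0.750,
        ("LYN", "PRKCA", "PLA2G4B", "GNAS", "GNAZ", "GNA12", "CRHR1",
         "GRM1", "GNAQ", "GNAI1"),
    ),
    (
        "path:00230_30", "Purine metabolism", 0.866,
        ("PDE1A", "GMPS", "ITPA", "POLR3A", "PDE2A", "ENTPD2", "RRM2",
         "ADCY7"),
    ),
    (
        "path:04151_102", "PI3K-Akt signalling pathway", -0.927,
        ("GH2", "JAK2", "IL2RG", "PIK3CD", "IRS1", "IL7R", "IGF1R",
         "FGF10", "FGF18"),
    ),
)


def published_signature() -> Signature:
    """The frozen four-subpathway signature as a :class:`Signature`."""
    return Signature(
        members=tuple(
            SignatureMember(sid, pathway, genes, beta)
            for sid, pathway, beta, genes in PUBLISHED_MEMBERS
        ),
        cutoff=PUBLISHED_CUTOFF,
        eq1_divisor="n",
        created_from={"source": "published breast-cancer training cohort"},
    )
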