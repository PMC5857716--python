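"""Published Photosystem I identity and calibration data.

These are the printed percent-identity comparisons of the PsaA and PsaB core
subunits of Photosystem I across species pairs of known (fossil-bracketed)
divergence age, and the fossil calibration table used for relaxed-clock
dating of the PsaA/PsaB gene duplication.  Divergence ages for land-plant
pairs are midpoints of hard-minimum/soft-maximum fossil brackets.
"""

from __future__ import annotations

from .seq_identity import IdentityRecord

__all__ = [
    "psa_identity_records",
    "PSA_AB_MEAN_IDENTITY_PCT",
    "psa_calibration_table",
]

# Mean PsaA-vs-PsaB identity across oxygenic phototrophs, the divergence
# level whose age the chronometer extrapolates.
PSA_AB_MEAN_IDENTITY_PCT = 42.5

# (pair, age_ma, age_min_ma, age_max_ma, identity A-vs-A, identity B-vs-B)
_PAIRS = [
    ("Arabidopsis thaliana vs Populus trichocarpa", 104.6, 82.0, 127.0, 98.6, 98.2),
    ("Chloranthus spicatus vs Liriodendron tulipifera", 173.2, None, None, 99.2, 99.1),
    ("A. thaliana vs C. spicatus", 186.2, None, None, 96.9, 97.6),
    ("A. thaliana vs Illicium oligandrum", 186.2, None, None, 96.6, 97.5),
    ("A. thaliana vs Nymphaea alba", 186.2, None, None, 97.3, 97.1),
    ("A. thaliana vs Amborella trichopoda", 186.2, None, None, 96.6, 96.4),
    ("Welwitschia mirabilis vs Pinus thunbergii", 215.65, None, None, 92.1, 93.1),
    ("W. mirabilis vs Ginkgo biloba", 236.75, None, None, 92.8, 94.0),
    ("W. mirabilis vs Cycas taitungensis", 336.5, None, None, 92.4, 94.5),
    ("A. thaliana vs Psilotum nudum", 421.1, None, None, 91.0, 91.1),
    ("A. thaliana vs Anthoceros formosae", 731.2, None, None, 91.4, 91.4),
    ("A. thaliana vs Physcomitrella patens", 731.2, None, None, 92.4, 92.5),
    ("A. thaliana vs Marchantia polymorpha", 745.5, 410.0, 680.0, 92.5, 92.5),
    ("A. thaliana vs Cyanidioschyzon merolae", 1450.0, 1100.0, 1800.0, 82.2, 80.9),
    ("A. thaliana vs Gloeobacter kilaueensis", 2500.0, 2000.0, 3000.0, 66.5, 72.8),
]

# Within-species PsaA-vs-PsaB identities (the duplication signal itself).
_A_VS_B = [
    ("Arabidopsis thaliana", 42.4),
    ("Marchantia polymorpha", 42.3),
    ("Cyanidioschyzon merolae", 42.3),
    ("Gloeobacter kilaueensis", 43.3),
]


def psa_identity_records() -> list[IdentityRecord]:
    """The published PsaA/PsaB identity table as IdentityRecord objects."""
    records = []
    for pair, age, lo, hi, ident_a, ident_b in _PAIRS:
        for subunit, ident in (("A-vs-A", ident_a), ("B-vs-B", ident_b)):
            records.append(
                IdentityRecord(
                    pair_label=pair,
                    subunit=subunit,
                    identity_pct=ident,
                    divergence_age_ma=age,
                    age_min_ma=lo,
                    age_max_ma=hi,
                )
            )
    for species, ident in _A_VS_B:
        records.append(
            IdentityRecord(pair_label=species, subunit="A-vs-B", identity_pct=ident)
        )
    return records


def psa_calibration_table() -> list[dict]:
    """Fossil calibration points for the Type I reaction-centre chronogram.

    Node labels follow the published numbering; ``None`` marks an absent
    bound.  Node 9 (MRCA of Cyanobacteria) is used with its 2450 Ma minimum
    by default; the 3000 Ma alternative and full removal are the standard
    sensitivity variants.
    """
    rows = [
        ("node1", "Arabidopsis-Populus divergence", 82.0, 127.0),
        ("node2", "Angiosperms", 124.0, 248.0),
        ("node3", "Gymnosperms", 306.0, 366.0),
        ("node4", "Land plants", 475.0, None),
        ("node5", "Diatoms", 190.0, None),
        ("node6", "Floridae", 600.0, None),
        ("node7", "MRCA of photosynthetic eukaryotes", 1600.0, None),
        ("node8", "Heterocystous Cyanobacteria", 1600.0, None),
        ("node9", "MRCA of Cyanobacteria", 2450.0, None),
    ]
    return [
        {"node_label": lbl, "event": event, "min_ma": lo, "max_ma": hi}
        for lbl, event, lo, hi in rows
    ]
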