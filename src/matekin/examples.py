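"""Small worked pedigrees exercising the kinship and inbreeding arithmetic.

Both constructions mirror classic field situations in a polygynous,
matrilineal study population: a male siring calves for related females of one
matriline (raising their offspring's relatedness), and intralineage polygyny
stacking extra loops onto an already-inbred mating.
"""

from __future__ import annotations

from .pedigree import FEMALE, MALE, Pedigree


def _ind(iid, sex, by, mother=None, father=None, matriline=None):
    return {
        "id": iid,
        "sex": sex,
        "birth_year": by,
        "death_year": None,
        "mother_id": mother,
        "father_id": father,
        "matriline_id": matriline,
    }


def aunt_half_niece_pedigree(shared_father: bool = True) -> Pedigree:
    """Aunt and half-niece, optionally also paternal half-sisters.

    ``AUNT`` is the maternal half-sister of ``NIECE``'s mother, making the
    pair aunt–half-niece (r = 0.125).  With ``shared_father=True`` the same
    male additionally sires both ``AUNT`` and ``NIECE`` — a male re-mating
    within one matriline — which adds a paternal half-sib link (r + 0.250
    = 0.375).  The pair of interest is (``AUNT``, ``NIECE``).
    """
    g = "GRANDMA"
    sire = "SHARED_SIRE"
    other = "OTHER_SIRE"
    recs = [
        _ind(g, FEMALE, 1970, matriline=g),
        _ind(sire, MALE, 1970),
        _ind(other, MALE, 1970),
        _ind("SISTER", FEMALE, 1975, mother=g, father=other, matriline=g),
        _ind("AUNT", FEMALE, 1980, mother=g, father=sire, matriline=g),
        _ind("NIECE", FEMALE, 1985, mother="SISTER",
             father=sire if shared_father else other, matriline=g),
    ]
    return Pedigree.from_records(recs)


def intralineage_inbreeding_pedigree() -> Pedigree:
    """Pedigree whose focal calf is inbred through three ancestral loops.

    The focal calf ``FOCAL``'s parents ``DAM`` and ``SIRE`` are
    simultaneously:

    * aunt–half-nephew — ``DAM`` and the sire's mother are maternal
      half-sisters (kinship contribution (1/2)^4 = 0.0625);
    * half first cousins once removed — one male (``B``) sired both the dam's
      father and the sire's grandmother, two females of the same matriline
      having mated with him (contribution (1/2)^6 = 0.015625);
    * half third cousins — one founder female (``C``) heads the maternal
      lines of both of those mates of ``B`` (contribution (1/2)^9
      = 0.001953125).

    Wright's f of ``FOCAL`` is the sum, 0.080078125, printed 0.08008 at five
    decimal places.
    """
    recs = [
        # founders
        _ind("C", FEMALE, 1960, matriline="C"),
        _ind("A1", FEMALE, 1964, matriline="A1"),
        _ind("B", MALE, 1960),
        _ind("FW", MALE, 1960),
        _ind("FW2", MALE, 1964),
        _ind("FV", MALE, 1960),
        _ind("FM", MALE, 1968),
        _ind("FQ", MALE, 1972),
        # matriline-C females, both of whom mated with B
        _ind("W2", FEMALE, 1964, mother="C", father="FW", matriline="C"),
        _ind("W", FEMALE, 1968, mother="W2", father="FW2", matriline="C"),
        _ind("V", FEMALE, 1965, mother="C", father="FV", matriline="C"),
        _ind("P", MALE, 1972, mother="W", father="B"),
        _ind("R", FEMALE, 1970, mother="V", father="B", matriline="C"),
        _ind("Q", MALE, 1975, mother="R", father="FQ"),
        # matriline-A1 half-sisters: the dam and the sire's mother
        _ind("DAM", FEMALE, 1978, mother="A1", father="P", matriline="A1"),
        _ind("M", FEMALE, 1974, mother="A1", father="FM", matriline="A1"),
        _ind("SIRE", MALE, 1980, mother="M", father="Q"),
        _ind("FOCAL", FEMALE, 1986, mother="DAM", father="SIRE",
             matriline="A1"),
    ]
    return Pedigree.from_records(recs)
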