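"""Built-in organism fixtures transcribed from the published trait tables.

Only a small, load-bearing subset of the published database is shipped:

* :func:`table1_records` — the five representative organisms used for the
  printed Reynolds-number table.  Values are the unrounded trait-table
  entries (the printed Reynolds table rounds its input column to 3
  significant figures but was computed from the unrounded traits; e.g. the
  bull spermatozoon body length is 8.87 µm, printed as 8.9).
* :func:`torque_bound_records` — the two species that set the lower and
  upper motor-torque bounds of the bacterial RFT analysis.
* :func:`ciliate_records` — representative ciliates with enough ciliation
  data for the per-cilium force model, plus speed-only rows.

Frequencies are stored as cycles s⁻¹; models apply the 2π conversion.
"""

from __future__ import annotations

import io

from .records import read_records, OrganismRecord

__all__ = ["table1_records", "torque_bound_records", "ciliate_records", "demo_records"]

# Columns: species,group,B,W,U,N,L,lam,h,n_w,f,ell,d,kappa,notes,refs
_TABLE1_CSV = """\
species,group,B,W,U,N,L,lam,h,n_w,f,ell,d,kappa,notes,refs
Escherichia coli,bacteria,2.5 ± 0.6,0.88 ± 0.09,24.1 ± 10 (14.2 − 60),6,8.3 ± 2.0,2.366 ± 0.121,0.38,2,131 ± 31,,,,peritrichous; flagella bundle while running,trait tables
Halobacterium salinarum,archaea,2.6 ± 0.5 (1.6 − 10),0.43 ± 0.07 (max 1),3.3 ± 0.9 (max 10),,4.3 ± 1,2.1 ± 0.2,0.22 ± 0.03,,23 ± 5,,,,mono- or bipolar tuft of archaella,trait tables
Giardia lamblia,flagellate,(10.4 − 12.1),(7.3 − 8.9),(12 − 40),8,(10.6 − 12.5),(2.73 − 5.5),(0.2 − 0.31),2,13,,,,beat frequency back-derived from the printed angular rate 81.7 rad/s,trait tables
Bull spermatozoon,spermatozoon,8.87 (6.77 − 10.2),4.74 (4.2 − 5.4),97 ± 6 (40 − 160),1,(44.2 − 63.83),(30.5 − 40),8 (7.1 − 11),1,20.57 ± 3.4,,,,3D helical or complex beat treated as planar,trait tables
Paramecium caudatum,ciliate,242 (140 − 311),48 (35 − 70),1476.5 (478.7 − 4500),,,,,,31.4 ± 8.3,12,,(0.5 − 11.1),body-region beat frequency; dexioplectic metachrony,trait tables
"""

_TORQUE_CSV = """\
species,group,B,W,U,N,L,lam,h,n_w,f,ell,d,kappa,notes,refs
Halobacterium salinarum,archaea,2.6 ± 0.5 (1.6 − 10),0.43 ± 0.07 (max 1),3.3 ± 0.9 (max 10),,4.3 ± 1,2.1 ± 0.2,0.22 ± 0.03,,23 ± 5,,,,lower torque bound,trait tables
Pseudomonas fluorescens,bacteria,3.1 ± 0.8,0.9 ± 0.1,77.6 (max 102),1.5 ± 1.1,8.4 ± 1.3,1.76,0.39,2.5,,,,,upper torque bound; run speed,trait tables
"""

_CILIATE_CSV = """\
species,group,B,W,U,N,L,lam,h,n_w,f,ell,d,kappa,notes,refs
Blepharisma sp.,ciliate,350,120,600,7000,,,,,,7.5,,0.1,compound cilia excluded from N,trait tables
Coleps hirtus,ciliate,(66 − 123),(30 − 72.9),686,,,,,,,24.7,10,,regular cilia spacing,trait tables
Didinium nasutum,ciliate,126 (80 − 200),83.1 (60 − 107),1190 (464 − 3000),1750,,,,,,12.5,,0.2,two circular ciliary rows,trait tables
Opalina ranarum,ciliate,375 (200 − 500),(112 − 300),50,100000,,,,,3.6 (1 − 5),15.35 (10 − 20),(0.33 − 3),1.2 (1 − 2),symplectic metachrony,trait tables
Paramecium caudatum,ciliate,242 (140 − 311),48 (35 − 70),1476.5 (478.7 − 4500),,,,,,31.4 ± 8.3,12,,(0.5 − 11.1),dexioplectic metachrony,trait tables
Spirostomum sp.,ciliate,1000,130,1000,100000,,,,,,12,,0.2,compound cilia excluded,trait tables
Tetrahymena pyriformis,ciliate,70 (55.7 − 89.77),27.5 (20 − 45),480 (451.2 − 500),500,,,,,20,(7 − 14.35),(2.84 − 6.16),0.2,dexio-antiplectic metachrony,trait tables
Uronema sp.,ciliate,25,11.25,(1150 − 1200),200,,,,,,5,,0.6,compound cilia excluded,trait tables
Stentor polymorphus,ciliate,208,(15.2 − 152),(817 − 957),,,,,,33,27.5,3.5,,dexioplectic metachrony,trait tables
Amphileptus gigas,ciliate,808,136,608,,,,,,,,,,speed-only row,trait tables
"""


def _load(csv_text: str) -> list[OrganismRecord]:
    records, diags = read_records(io.StringIO(csv_text), fmt="csv")
    fatal = [d for d in diags if d.fatal]
    if fatal:  # shipped fixtures must always validate
        raise RuntimeError(f"fixture failed validation: {fatal}")
    return records


def table1_records() -> list[OrganismRecord]:
    """The five representative organisms of the Reynolds-number table."""
    return _load(_TABLE1_CSV)


def torque_bound_records() -> list[OrganismRecord]:
    """The species setting the 27.48 and 1907 pN·nm motor-torque bounds."""
    return _load(_TORQUE_CSV)


def ciliate_records() -> list[OrganismRecord]:
    """Representative ciliates, including the per-cilium force cohort."""
    return _load(_CILIATE_CSV)


def demo_records() -> list[OrganismRecord]:
    """Union of all shipped fixtures (species de-duplicated)."""
    seen: set[str] = set()
    out: list[OrganismRecord] = []
    for rec in table1_records() + torque_bound_records() + ciliate_records():
        if rec.species not in seen:
            seen.add(rec.species)
            out.append(rec)
    return out
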