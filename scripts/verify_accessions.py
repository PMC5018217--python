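"""Optional integration check against public genome assemblies (needs network).

Downloads the Polynucleobacter assemblies the packaged ANI table refers to
(CP000655, CP001010, LOJI01 contigs, ...) from NCBI E-utilities, then
recomputes with this package:

* genome statistics (expected: CP000655 -> 2.16 Mbp, 44.8 mol% G+C),
* fragment-based symmetric ANI for selected pairs (expected: CP001010 vs
  the LOJI01 assembly about 84.1 %, within about one ANI point across
  aligner choices).

This is an integration script, not part of the test suite: it requires
internet access and several hundred megabytes of downloads, so run it
manually:

    python scripts/verify_accessions.py --workdir scratch/accessions
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

from anitax.ani import AniParams, ani_oneway, symmetric_ani
from anitax.diagnostics import genome_stats
from anitax.seqio import read_fasta

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

#: accession -> (strain, expected size Mbp, expected G+C mol%)
GENOMES = {
    "CP000655": ("QLW-P1DMWA-1", 2.16, 44.8),
    "CP001010": ("STIR1", 1.56, 45.6),
    "CP007501": ("MWH-MoK4", 2.03, 45.2),
}

#: (query accession, subject accession, expected symmetric ANI)
ANI_PAIRS = [("CP001010", "CP000655", 78.0), ("CP001010", "CP007501", 76.1)]


def fetch(accession: str, dest: Path) -> Path:
    path = dest / f"{accession}.fasta"
    if path.exists():
        return path
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "fasta", "retmode": "text"})
    print(f"fetching {accession} ...", flush=True)
    with urllib.request.urlopen(f"{EUTILS}?{query}", timeout=120) as resp:
        path.write_bytes(resp.read())
    time.sleep(1)  # E-utilities rate limit
    return path


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workdir", type=Path, default=Path("scratch/accessions"))
    args = parser.parse_args()
    args.workdir.mkdir(parents=True, exist_ok=True)

    genomes = {}
    failures = 0
    for acc, (strain, size_mbp, gc) in GENOMES.items():
        g = read_fasta(fetch(acc, args.workdir), mode="genome", genome_id=strain)[0]
        genomes[acc] = g
        stats = genome_stats(g)
        ok = stats["size_mbp"] == size_mbp and stats["gc_molpct"] == gc
        failures += not ok
        print(f"{acc} ({strain}): {stats['size_mbp']} Mbp, {stats['gc_molpct']} mol% "
              f"[expected {size_mbp} / {gc}] {'OK' if ok else 'MISMATCH'}")

    params = AniParams()
    for qa, sa, expected in ANI_PAIRS:
        fwd = ani_oneway(genomes[qa], genomes[sa], params)
        rev = ani_oneway(genomes[sa], genomes[qa], params)
        sym = symmetric_ani(fwd, rev)
        ok = sym is not None and abs(sym - expected) <= 1.0
        failures += not ok
        print(f"ANI {qa} vs {sa}: {sym:.2f} [expected {expected} +/- 1.0] "
              f"{'OK' if ok else 'MISMATCH'}")
    return 1 if failures else 0


if __name__ == "__main__":
    sys.exit(main())
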