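"""Optional retrieval of the deposited Muricidae hemocyanin records.

The deposited coding sequences (NCBI) are:

======  ==========
RtH1    BK014286
RtH2    BK014287
NlH1    MT939254
NlH2    MT939255
======  ==========

Fetching requires network access and is never needed to build or test the
package; every pipeline stage runs on synthetic data.  These helpers exist so
the characterization stages can be pointed at the real subunits when a
connection is available.
"""

from __future__ import annotations

import socket

ACCESSIONS = {
    "RtH1": "BK014286",
    "RtH2": "BK014287",
    "NlH1": "MT939254",
    "NlH2": "MT939255",
}

_EUTILS_HOST = "eutils.ncbi.nlm.nih.gov"


def network_available(timeout: float = 3.0) -> bool:
    """True when the NCBI E-utilities host answers on port 443."""
    try:
        with socket.create_connection((_EUTILS_HOST, 443), timeout=timeout):
            return True
    except OSError:
        return False


def fetch_cds(accession: str, email: str = "hemasm@example.org", timeout: float = 60.0) -> str:
    """Download the (first) annotated CDS of a nucleotide record as a string."""
    from io import StringIO

    from Bio import Entrez, SeqIO

    Entrez.email = email
    with Entrez.efetch(
        db="nuccore", id=accession, rettype="fasta_cds_na", retmode="text"
    ) as handle:
        text = handle.read()
    records = list(SeqIO.parse(StringIO(text), "fasta"))
    if not records:
        raise ValueError(f"no CDS found in record {accession}")
    return str(records[0].seq).upper()
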