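"""Search and filter report writers: tab-delimited and pepXML.

The tab-delimited search report carries one row per reported PSM and is the
interchange format between the `search` and `filter` stages; pepXML output
exposes the three scores as named ``search_score`` entries for third-party
filtering tools.
"""

from __future__ import annotations

from pathlib import Path

from lxml import etree

from .scoring import PSM
from .seqdb import PeptideCandidate, peptide_mass

SEARCH_COLUMNS = [
    "scan_id", "peptide", "proteins", "charge", "delta_mass",
    "mvh", "xcorr", "wdp", "rank_mvh", "rank_xcorr", "rank_wdp",
    "is_decoy", "missed_cleavages",
]


def write_search_tsv(by_scan: dict[str, list[PSM]], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEARCH_COLUMNS) + "\n")
        for scan in sorted(by_scan):
            for p in by_scan[scan]:
                row = [
                    p.scan_id,
                    p.sequence,
                    ";".join(sorted(p.peptide.parent_protein_ids)),
                    str(p.charge),
                    f"{p.delta_mass:.6f}",
                    f"{p.mvh:.6f}",
                    f"{p.xcorr:.6f}",
                    f"{p.wdp:.6f}",
                    str(p.rank_mvh),
                    str(p.rank_xcorr),
                    str(p.rank_wdp),
                    str(int(p.is_decoy)),
                    str(p.peptide.missed_cleavages),
                ]
                fh.write("\t".join(row) + "\n")


def read_search_tsv(path) -> dict[str, list[PSM]]:
    """Rebuild per-scan PSM lists from a search report."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"search report {path} is empty")
    header = lines[0].split("\t")
    missing = [c for c in SEARCH_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"search report is missing columns: {', '.join(missing)}")
    col = {c: header.index(c) for c in SEARCH_COLUMNS}
    by_scan: dict[str, list[PSM]] = {}
    for line in lines[1:]:
        v = line.split("\t")
        seq = v[col["peptide"]]
        cand = PeptideCandidate(
            sequence=seq,
            neutral_mass=peptide_mass(seq),
            missed_cleavages=int(v[col["missed_cleavages"]]),
            parent_protein_ids=set(v[col["proteins"]].split(";")),
            is_decoy=bool(int(v[col["is_decoy"]])),
        )
        psm = PSM(
            scan_id=v[col["scan_id"]],
            peptide=cand,
            charge=int(v[col["charge"]]),
            mvh=float(v[col["mvh"]]),
            xcorr=float(v[col["xcorr"]]),
            wdp=float(v[col["wdp"]]),
            rank_mvh=int(v[col["rank_mvh"]]),
            rank_xcorr=int(v[col["rank_xcorr"]]),
            rank_wdp=int(v[col["rank_wdp"]]),
            delta_mass=float(v[col["delta_mass"]]),
        )
        by_scan.setdefault(psm.scan_id, []).append(psm)
    return by_scan


_PEPXML_NS = "http://regis-web.systemsbiology.net/pepXML"


def write_pepxml(by_scan: dict[str, list[PSM]], path, search_engine: str = "triscore") -> None:
    """One spectrum_query per (scan, assumed charge); one search_hit per
    reported PSM with mvh/xcorr/wdp as named search_score entries."""
    root = etree.Element(
        f"{{{_PEPXML_NS}}}msms_pipeline_analysis",
        nsmap={None: _PEPXML_NS},
        summary_xml=str(path),
    )
    run = etree.SubElement(root, f"{{{_PEPXML_NS}}}msms_run_summary",
                           base_name=str(path), raw_data_type="raw", raw_data=".mgf")
    etree.SubElement(
        run, f"{{{_PEPXML_NS}}}search_summary",
        base_name=str(path), search_engine=search_engine,
        precursor_mass_type="monoisotopic", fragment_mass_type="monoisotopic",
        search_id="1",
    )
    qid = 0
    for scan in sorted(by_scan):
        psms = by_scan[scan]
        if not psms:
            continue
        qid += 1
        charge = psms[0].charge
        neutral = psms[0].peptide.neutral_mass + psms[0].delta_mass  # representative
        query = etree.SubElement(
            run, f"{{{_PEPXML_NS}}}spectrum_query",
            spectrum=scan, start_scan=str(qid), end_scan=str(qid),
            precursor_neutral_mass=f"{neutral:.6f}",
            assumed_charge=str(charge), index=str(qid),
        )
        result = etree.SubElement(query, f"{{{_PEPXML_NS}}}search_result")
        for rank, p in enumerate(psms, start=1):
            parents = sorted(p.peptide.parent_protein_ids)
            hit = etree.SubElement(
                result, f"{{{_PEPXML_NS}}}search_hit",
                hit_rank=str(rank), peptide=p.sequence,
                protein=parents[0],
                num_tot_proteins=str(len(parents)),
                calc_neutral_pep_mass=f"{p.peptide.neutral_mass:.6f}",
                massdiff=f"{p.delta_mass:.6f}",
                num_missed_cleavages=str(p.peptide.missed_cleavages),
                is_rejected="0",
            )
            for alt in parents[1:]:
                etree.SubElement(hit, f"{{{_PEPXML_NS}}}alternative_protein", protein=alt)
            for name in ("mvh", "xcorr", "wdp"):
                etree.SubElement(
                    hit, f"{{{_PEPXML_NS}}}search_score",
                    name=name, value=f"{getattr(p, name):.6f}",
                )
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def write_filter_tsv(selected, result, peptide_fdr, protein_fdr, path) -> None:
    """Per-spectrum selected PSM with features, classification score,
    agreement class and accepted flag; summary lines are '#'-prefixed."""
    from .filtering import FEATURE_NAMES

    accepted_ids = {id(c) for c in result.accepted}
    with open(path, "w") as fh:
        fh.write(f"# level={result.level} threshold={result.threshold:.6g}\n")
        fh.write(
            f"# psm_fdr={result.fdr.fdr:.6g} n_target={result.fdr.n_target}"
            f" n_test_decoy={result.fdr.n_test_decoy} alpha={result.fdr.alpha:.4f}\n"
        )
        if peptide_fdr is not None:
            fh.write(f"# peptide_fdr={peptide_fdr.fdr:.6g} n_target_peptides={peptide_fdr.n_target}\n")
        if protein_fdr is not None:
            fh.write(f"# protein_fdr={protein_fdr.fdr:.6g} n_target_groups={protein_fdr.n_target}\n")
        cols = ["scan_id", "peptide", "charge", "is_decoy", "decoy_split",
                "agreement", "classification_score", "accepted", *FEATURE_NAMES]
        fh.write("\t".join(cols) + "\n")
        for scan in sorted(selected):
            c = selected[scan]
            row = [
                scan, c.psm.sequence, str(c.psm.charge), str(int(c.is_decoy)),
                c.decoy_split.value, c.agreement.value,
                f"{c.classification_score:.6f}",
                str(int(id(c) in accepted_ids)),
                *(f"{x:.6f}" for x in c.features),
            ]
            fh.write("\t".join(row) + "\n")


def write_peptides_tsv(peptides, path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tspectrum_count\tproteins\tis_decoy\tdecoy_split\n")
        for p in peptides:
            fh.write(
                f"{p.sequence}\t{p.spectrum_count}\t"
                f"{';'.join(sorted(p.parent_protein_ids))}\t{int(p.is_decoy)}\t"
                f"{p.decoy_split.value}\n"
            )


def write_proteins_tsv(groups, path) -> None:
    with open(path, "w") as fh:
        fh.write("members\tn_peptides\tn_unique_peptides\tis_decoy\tdecoy_split\n")
        for g in groups:
            fh.write(
                f"{';'.join(g.member_ids)}\t{len(g.peptides)}\t"
                f"{len(g.unique_peptides)}\t{int(g.is_decoy)}\t{g.decoy_split.value}\n"
            )
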