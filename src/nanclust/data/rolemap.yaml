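# Role map: which domain/homology evidence supports which SAC gene role,
# and the thresholds each evidence channel must pass.
#
# NOTE: the Pfam/CDD accessions per role are a reconstruction from widely
# cited family assignments for each enzyme (NanA = DHDPS-family lyase,
# NanK = ROK-family kinase, NanE = NanE-family epimerase, ...); edit this
# file to match your own annotation conventions.  The transporter family
# accessions (PF00496 SBP_bac_5, PF01547 SBP_bac_1, PF00528 BPD_transp_1)
# and regulator/mobilome COG ids are the standard ones for sialic acid
# transport and regulation.
#
# Threshold semantics are strict: a hit passes iff evalue < evalue_max,
# identity_pct > identity_min (when set) and coverage_pct > coverage_min
# (when set).  A role listing require_sources needs at least one passing
# pattern from every listed source (two-channel confirmation for the core
# nanA/K/E roles); other roles need any one passing pattern.
# accession "*" matches any accession from that source.

source_thresholds:
  pfam:     {evalue_max: 1.0e-10}
  cdd:      {evalue_max: 1.0e-10}
  blastp:   {evalue_max: 1.0e-5, identity_min: 30}
  cog:      {evalue_max: 1.0e-5, identity_min: 50, coverage_min: 50}
  isfinder: {evalue_max: 1.0e-5}
  itseg:    {evalue_max: 1.0e-10}

roles:
  nanA:
    require_sources: [pfam, cdd]
    patterns:
      - {source: pfam, accession: PF00701}   # DHDPS family (Neu5Ac lyase)
      - {source: cdd,  accession: cd00954}   # NAL
  nanK:
    require_sources: [pfam, cdd]
    patterns:
      - {source: pfam, accession: PF00480}   # ROK family (ManNAc kinase)
      - {source: cdd,  accession: cd24069}
  nanE:
    require_sources: [pfam, cdd]
    patterns:
      - {source: pfam, accession: PF04131}   # NanE (ManNAc-6P epimerase)
      - {source: cdd,  accession: cd04729}
  nagA:
    patterns:
      - {source: pfam, accession: PF01979}   # Amidohydro_1 (GlcNAc-6P deacetylase)
  nagB:
    patterns:
      - {source: pfam, accession: PF01182}   # Glucosamine_iso (GlcN-6P deaminase)
  sialidase:
    patterns:
      - {source: pfam, accession: PF13088}   # BNR_2 repeats
      - {source: pfam, accession: PF02973}   # sialidase lectin-like
  it_sialidase_segment:
    patterns:
      - {source: itseg, accession: RgNanH_seg}  # segmented RgNanH-type domain model
  nanE_II:
    patterns:
      - {source: blastp, accession: NANE2_REF}  # GlcNAc epimerase reference protein
  rokA:
    patterns:
      - {source: blastp, accession: ROKA_REF}   # glucokinase reference protein
  nanOx:
    patterns:
      - {source: blastp, accession: NANOX_REF}  # anhydro-Neu5Ac oxidoreductase
  transporter_ABC_ST3:
    patterns:
      - {source: pfam, accession: PF00496}   # SBP_bac_5 (Neu5Ac ABC SBP, ST3)
  transporter_ABC_ST7:
    patterns:
      - {source: pfam, accession: PF01547}   # SBP_bac_1 (anhydro-Neu5Ac ABC SBP, ST7)
  transporter_ABC_partial:
    patterns:
      - {source: pfam, accession: PF00528}   # BPD_transp_1 (permease component only)
  transporter_MFS:
    patterns:
      - {source: pfam, accession: PF07690}   # MFS_1
  transporter_SSS:
    patterns:
      - {source: pfam, accession: PF00474}   # SSF (sodium:solute symporter)
  regulator:
    patterns:
      - {source: cog, accession: COG2186}    # FadR-family (GntR)
      - {source: cog, accession: COG1349}    # GlpR (DeoR-family)
      - {source: cog, accession: COG1481}    # WhiA
      - {source: cog, accession: COG2207}    # AcrR/AraC-family
      - {source: cog, accession: K}          # COG functional category K
  IS:
    patterns:
      - {source: isfinder, accession: "*"}
  mobilome:
    patterns:
      - {source: cog, accession: X}          # COG functional category X
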