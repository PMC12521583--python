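# Default functional-category skeleton for phage protein annotation.
#
# Roots are independent general molecular-function groups; subcategories
# refine them.  A term may appear under several categories ("tail protein
# with lytic activity" is a tail protein AND a cell wall depolymerase).
# This inventory is a representative skeleton, not a complete vocabulary:
# supply your own ontology file for production annotation runs.
categories:
  pvp:
    parent: null
    terms:
      - phage virion protein
      - virion structural protein
      - head-tail adaptor
      - portal protein
      - neck protein
  tail:
    parent: pvp
    terms:
      - tail protein
      - major tail protein
      - minor tail protein
      - tail fiber protein
      - tail spike protein
      - tail length tape measure protein
      - tail protein with lytic activity
      - distal tail protein
  capsid:
    parent: pvp
    terms:
      - major capsid protein
      - minor capsid protein
      - capsid maturation protease
      - head scaffolding protein
  baseplate:
    parent: pvp
    terms:
      - baseplate protein
      - baseplate wedge subunit
      - baseplate hub protein
      - baseplate spike
  collar:
    parent: pvp
    min_train_clusters: 50
    terms:
      - collar protein
      - upper collar protein
      - lower collar protein
  internal:
    parent: pvp
    terms:
      - internal virion protein
      - ejection protein
      - internal virion protein with endolysin domain
  lysis:
    parent: null
    terms:
      - lysis protein
      - lysis inhibition protein
  lysin:
    parent: lysis
    terms:
      - endolysin
      - lysin
      - n-acetylmuramoyl-l-alanine amidase
      - lysozyme
      - internal virion protein with endolysin domain
  holin:
    parent: lysis
    terms:
      - holin
      - antiholin
      - pinholin
  spanin:
    parent: lysis
    terms:
      - spanin
      - i-spanin
      - o-spanin
      - u-spanin
  DNA-associated:
    parent: null
    terms:
      - dna binding protein
      - dna polymerase
      - helicase
      - primase
      - ssdna binding protein
      - replication initiation protein
  nuclease:
    parent: DNA-associated
    terms:
      - endonuclease
      - exonuclease
      - homing endonuclease
      - hnh endonuclease
      - recombination endonuclease
  integration:
    parent: DNA-associated
    terms:
      - integrase
      - tyrosine integrase
      - serine integrase
      - excisionase
      - recombinase
  transcriptional regulator:
    parent: DNA-associated
    terms:
      - transcriptional regulator
      - transcriptional repressor
      - transcriptional activator
      - anti-repressor
      - sigma factor
  cell wall depolymerase:
    parent: null
    terms:
      - tail protein with lytic activity
      - exopolysaccharide depolymerase
      - virion-associated lysin
      - peptidoglycan hydrolase
      - tail spike protein
  transferase:
    parent: null
    terms:
      - glycosyltransferase
      - methyltransferase
      - acetyltransferase
      - nucleotidyltransferase
  packaging:
    parent: null
    terms:
      - terminase large subunit
      - terminase small subunit
      - dna packaging protein
      - packaging atpase
overrides:
  # Regulators with DNA-binding annotations count as positives for the
  # broad DNA-associated model; purely generic ones are left out of both
  # classes for that model.
  - term: transcriptional regulator
    category: DNA-associated
    directive: force_positive
  - term: putative regulatory protein
    category: DNA-associated
    directive: exclude
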