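# Default Boolean screening query: FSW AND (HIV OR Violence).
# Each category lists MeSH headings and free-text (TW) terms; a trailing "*"
# marks prefix (truncation) matching on the last word of the pattern.
# Acronyms deliberately carry no wildcard so they only match whole tokens.
FSW:
  mesh:
    - Prostitution
    - Sex Worker
  text:
    - prostitut*
    - commercial sex
    - transactional sex
    - sw
    - fsw
    - csw
    - sex trade
    - trade sex
HIV:
  mesh:
    - HIV
    - Acquired Immunodeficiency Syndrome
    - HIV Infections
  text:
    - human immunodeficiency virus*
    - acquired immunodeficiency syndrome*
    - hiv
    - aids
Violence:
  mesh:
    - Violence
    - Domestic Violence
    - Workplace Violence
    - Crime Victims
    - Battered Women
    - Rape
    - Homicide
    - Coercion
  text:
    - violen*
    - crime*
    - offense*
    - abuse*
    - victim*
    - rape*
    - assault*
    - batter*
    - extort*
    - intimidat*
    - exploit*
    - ipv
    - ipsv
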