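# Default 15 semantic token clusters (hiv, fsw, violence, offense, abuse,
# torture, rape, victim, assault, harass, extort, homicide, coercion, ipv,
# exploit).  Membership patterns are matched against the POST-STEMMING
# vocabulary; a trailing "*" means prefix match.  The cluster names follow
# the published scheme, but the membership lists are a reconstruction routed
# from the screening-query vocabulary (the original lists were not released);
# edit this file to refine them.  A token joins the first matching cluster
# in file order.
hiv:
  - hiv
  - aid
  - immunodefici*
fsw:
  - fsw
  - csw
  - sw
  - prostitut*
  - sex
  - trade
violence:
  - violen*
  - batter*
offense:
  - offens*
  - offenc*
  - crime*
  - crimin*
abuse:
  - abus*
torture:
  - tortur*
rape:
  - rape*
  - rapist*
victim:
  - victim*
assault:
  - assault*
harass:
  - harass*
extort:
  - extort*
homicide:
  - homicid*
coercion:
  - coerc*
  - intimid*
ipv:
  - ipv
  - ipsv
exploit:
  - exploit*
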