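macroareas:
- id: North
  strip:
  - Piemonte
  - Emilia Romagna
  - Toscana
  - NITp
  regions:
  - name: Piemonte
    center: Piemonte
    production: 121
  - name: Emilia Romagna
    center: Emilia Romagna
    production: 142
  - name: Toscana
    center: Toscana
    production: 167
  - name: Lombardia
    center: NITp
    production: 226
  - name: Veneto
    center: NITp
    production: 130
  - name: Friuli Venezia Giulia
    center: NITp
    production: 0
  - name: Trentino-Alto Adige
    center: NITp
    production: 0
  - name: Liguria
    center: NITp
    production: 0
  - name: Marche
    center: NITp
    production: 0
  - name: Valle d'Aosta
    center: null
    production: 0
  - name: Sardegna
    center: null
    production: 0
- id: South
  strip:
  - Lazio
  - Sicilia
  regions:
  - name: Lazio
    center: Lazio
    production: 117
  - name: Sicilia
    center: Sicilia
    production: 50
  - name: Calabria
    center: null
    production: 0
  - name: Basilicata
    center: null
    production: 0
  - name: Abruzzo-Molise
    center: null
    production: 0
  - name: Umbria
    center: null
    production: 0
  - name: Campania
    center: null
    production: 0
  - name: Puglia
    center: null
    production: 0
centers:
- id: Piemonte
  acceptance_rate: 0.26
  member_regions:
  - Piemonte
- id: Emilia Romagna
  acceptance_rate: 0.26
  member_regions:
  - Emilia Romagna
- id: Toscana
  acceptance_rate: 0.26
  member_regions:
  - Toscana
- id: NITp
  acceptance_rate: 0.26
  member_regions:
  - Friuli Venezia Giulia
  - Liguria
  - Lombardia
  - Marche
  - Trentino-Alto Adige
  - Veneto
- id: Lazio
  acceptance_rate: 0.26
  member_regions:
  - Lazio
- id: Sicilia
  acceptance_rate: 0.26
  member_regions:
  - Sicilia
fallback_mode: cascade
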