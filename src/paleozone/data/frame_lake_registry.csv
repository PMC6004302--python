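taxon_id,display_name,functional_group,in_dc_ratio,notes
Arcella vulgaris,Arcella vulgaris,other,False,excluded from D/C ratio
"Centropyxis aculeata ""aculeata""","Centropyxis aculeata ""aculeata""",centropyxid,True,
"Centropyxis aculeata ""discoides""","Centropyxis aculeata ""discoides""",centropyxid,True,
"Centropyxis constricta ""aerophila""","Centropyxis constricta ""aerophila""",centropyxid,True,
"Centropyxis constricta ""constricta""","Centropyxis constricta ""constricta""",centropyxid,True,
"Centropyxis constricta ""spinosa""","Centropyxis constricta ""spinosa""",centropyxid,True,
Centropyxis pontigulasiformis,Centropyxis pontigulasiformis,centropyxid,True,
Cucurbitella tricuspis,Cucurbitella tricuspis,difflugiid,False,planktic eutrophication indicator; excluded from D/C ratio
Difflugia bidens,Difflugia bidens,difflugiid,True,
"Difflugia urceolata ""urceolata""","Difflugia urceolata ""urceolata""",difflugiid,True,
"Difflugia urceolata ""elongata""","Difflugia urceolata ""elongata""",difflugiid,True,
Difflugia urens,Difflugia urens,difflugiid,True,
Lesquereusia spiralis,Lesquereusia spiralis,difflugiid,True,
Lagenodifflugia vas,Lagenodifflugia vas,difflugiid,True,
Pontigulasia compressa,Pontigulasia compressa,difflugiid,True,
"Difflugia glans ""magna""","Difflugia glans ""magna""",difflugiid,True,
"Difflugia glans ""distenda""","Difflugia glans ""distenda""",difflugiid,True,
Mediolus corona,Mediolus corona,difflugiid,True,also spelled 'Medilous corona'
"Difflugia oblonga ""oblonga""","Difflugia oblonga ""oblonga""",difflugiid,True,
"Difflugia oblonga ""spinosa""","Difflugia oblonga ""spinosa""",difflugiid,True,
"Difflugia oblonga ""lanceolata""","Difflugia oblonga ""lanceolata""",difflugiid,True,
"Difflugia oblonga ""tenuis""","Difflugia oblonga ""tenuis""",difflugiid,True,
"Difflugia oblonga ""glans""","Difflugia oblonga ""glans""",difflugiid,True,
"Difflugia oblonga ""triangularis""","Difflugia oblonga ""triangularis""",difflugiid,True,
"Difflugia oblonga ""linearis""","Difflugia oblonga ""linearis""",difflugiid,True,
"Difflugia protaeiformis ""protaeiformis""","Difflugia protaeiformis ""protaeiformis""",difflugiid,True,
"Difflugia protaeiformis ""claviformis""","Difflugia protaeiformis ""claviformis""",difflugiid,True,
"Difflugia protaeiformis ""curvicaulis""","Difflugia protaeiformis ""curvicaulis""",difflugiid,True,
"Difflugia protaeiformis ""amphoralis""","Difflugia protaeiformis ""amphoralis""",difflugiid,True,
"Difflugia protaeiformis ""acuminata""","Difflugia protaeiformis ""acuminata""",difflugiid,True,
"Difflugia protaeiformis ""scapellum""","Difflugia protaeiformis ""scapellum""",difflugiid,True,
Conicocassis potigulasiformis,Conicocassis potigulasiformis,difflugiid,True,
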