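sample_id,depth_top,depth_bottom,Arcella vulgaris,"Centropyxis aculeata ""aculeata""","Centropyxis aculeata ""discoides""","Centropyxis constricta ""aerophila""","Centropyxis constricta ""constricta""","Centropyxis constricta ""spinosa""",Centropyxis pontigulasiformis,Cucurbitella tricuspis,Difflugia bidens,"Difflugia urceolata ""urceolata""","Difflugia urceolata ""elongata""",Difflugia urens,Lesquereusia spiralis,Lagenodifflugia vas,Pontigulasia compressa,"Difflugia glans ""magna""","Difflugia glans ""distenda""",Medilous corona,"Difflugia oblonga ""oblonga""","Difflugia oblonga ""spinosa""","Difflugia oblonga ""lanceolata""","Difflugia oblonga ""tenuis""","Difflugia oblonga ""glans""","Difflugia oblonga ""triangularis""","Difflugia oblonga ""linearis""","Difflugia protaeiformis ""protaeiformis""","Difflugia protaeiformis ""claviformis""","Difflugia protaeiformis ""curvicaulis""","Difflugia protaeiformis ""amphoralis""","Difflugia protaeiformis ""acuminata""","Difflugia protaeiformis ""scapellum""",Conicocassis potigulasiformis
FL1,0,1,0.0,0.01,0.01,0.15,0.04,0.0,0.0,0.19,0.0,0.0,0.0,0.01,0.02,0.03,0.01,0.0,0.0,0.04,0.1,0.15,0.0,0.03,0.04,0.0,0.0,0.0,0.0,0.0,0.13,0.01,0.0,0.0
FL2,1,2,0.0,0.03,0.03,0.08,0.02,0.0,0.0,0.39,0.0,0.0,0.0,0.0,0.02,0.0,0.0,0.0,0.01,0.02,0.11,0.11,0.0,0.07,0.01,0.0,0.0,0.01,0.01,0.02,0.03,0.02,0.0,0.0
FL3,2,3,0.0,0.01,0.04,0.23,0.05,0.01,0.0,0.18,0.01,0.0,0.01,0.0,0.01,0.01,0.01,0.0,0.0,0.02,0.07,0.11,0.0,0.04,0.01,0.0,0.0,0.01,0.09,0.02,0.0,0.04,0.0,0.0
FL4,3,4,0.0,0.04,0.04,0.1,0.04,0.0,0.0,0.22,0.01,0.0,0.01,0.01,0.03,0.01,0.0,0.0,0.01,0.03,0.1,0.19,0.0,0.0,0.0,0.01,0.0,0.0,0.01,0.0,0.09,0.02,0.0,0.0
FL5,4,5,0.0,0.03,0.05,0.13,0.07,0.0,0.01,0.15,0.03,0.0,0.01,0.05,0.0,0.01,0.0,0.01,0.01,0.0,0.03,0.02,0.0,0.08,0.12,0.01,0.0,0.0,0.07,0.01,0.09,0.01,0.0,0.0
FL6,5,6,0.0,0.05,0.03,0.13,0.07,0.0,0.0,0.19,0.01,0.0,0.07,0.0,0.02,0.0,0.0,0.0,0.0,0.01,0.04,0.26,0.0,0.03,0.01,0.01,0.01,0.01,0.01,0.0,0.01,0.0,0.0,0.0
FL7,6,7,0.02,0.13,0.18,0.23,0.1,0.0,0.0,0.18,0.0,0.0,0.02,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.04,0.07,0.0,0.01,0.0,0.0,0.0,0.01,0.01,0.0,0.0,0.0,0.0,0.0
FL8,7,8,0.0,0.14,0.14,0.23,0.14,0.02,0.0,0.1,0.0,0.0,0.0,0.0,0.04,0.01,0.01,0.01,0.0,0.01,0.04,0.02,0.0,0.01,0.06,0.0,0.0,0.01,0.0,0.0,0.02,0.01,0.0,0.01
FL9,8,9,0.0,0.14,0.12,0.27,0.14,0.02,0.0,0.03,0.0,0.01,0.01,0.03,0.01,0.01,0.0,0.0,0.0,0.02,0.01,0.01,0.0,0.0,0.07,0.0,0.0,0.01,0.01,0.01,0.06,0.01,0.0,0.0
FL10,9,10,0.01,0.1,0.06,0.17,0.19,0.01,0.0,0.18,0.0,0.0,0.04,0.0,0.0,0.0,0.0,0.0,0.0,0.04,0.1,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.08,0.0,0.0,0.0
FL11,10,11,0.01,0.17,0.1,0.17,0.16,0.0,0.0,0.06,0.01,0.01,0.01,0.02,0.02,0.01,0.0,0.0,0.0,0.01,0.05,0.0,0.0,0.0,0.04,0.0,0.0,0.01,0.06,0.01,0.06,0.02,0.0,0.0
FL12,11,12,0.01,0.07,0.07,0.26,0.23,0.0,0.0,0.05,0.03,0.01,0.02,0.0,0.01,0.01,0.0,0.0,0.0,0.01,0.07,0.0,0.0,0.01,0.09,0.0,0.0,0.0,0.03,0.0,0.04,0.0,0.0,0.0
FL13,12,13,0.0,0.07,0.06,0.27,0.28,0.0,0.0,0.04,0.0,0.03,0.01,0.0,0.01,0.0,0.0,0.0,0.0,0.0,0.05,0.0,0.0,0.01,0.09,0.0,0.0,0.01,0.04,0.0,0.04,0.0,0.0,0.0
FL14,13,14,0.0,0.07,0.05,0.21,0.18,0.0,0.0,0.04,0.0,0.02,0.04,0.01,0.01,0.01,0.01,0.0,0.0,0.01,0.09,0.0,0.0,0.01,0.09,0.0,0.0,0.01,0.06,0.0,0.1,0.0,0.0,0.0
FL15,14,15,0.0,0.07,0.06,0.29,0.16,0.01,0.0,0.03,0.01,0.0,0.02,0.02,0.0,0.0,0.0,0.0,0.02,0.0,0.05,0.01,0.02,0.03,0.03,0.0,0.01,0.01,0.07,0.01,0.06,0.01,0.0,0.0
FL16,15,16,0.0,0.03,0.05,0.2,0.15,0.02,0.0,0.04,0.01,0.03,0.04,0.02,0.01,0.0,0.0,0.0,0.0,0.01,0.09,0.03,0.01,0.02,0.06,0.0,0.0,0.01,0.11,0.01,0.07,0.0,0.0,0.0
FL17,16,17,0.0,0.11,0.09,0.11,0.04,0.02,0.0,0.01,0.0,0.01,0.03,0.03,0.0,0.02,0.01,0.0,0.01,0.0,0.2,0.06,0.0,0.05,0.03,0.0,0.0,0.03,0.03,0.01,0.11,0.01,0.0,0.0
FL18,17,18,0.0,0.06,0.09,0.1,0.06,0.01,0.0,0.01,0.0,0.0,0.07,0.02,0.0,0.02,0.0,0.0,0.03,0.0,0.19,0.02,0.0,0.02,0.03,0.0,0.0,0.04,0.07,0.01,0.14,0.02,0.0,0.0
FL19,18,19,0.0,0.14,0.05,0.14,0.08,0.01,0.0,0.01,0.01,0.01,0.03,0.0,0.0,0.02,0.0,0.0,0.03,0.0,0.22,0.01,0.0,0.01,0.05,0.0,0.0,0.05,0.04,0.0,0.09,0.0,0.0,0.0
FL20,19,20,0.0,0.13,0.03,0.07,0.09,0.01,0.0,0.0,0.0,0.0,0.05,0.02,0.01,0.01,0.01,0.0,0.01,0.0,0.25,0.01,0.0,0.03,0.05,0.0,0.01,0.01,0.06,0.0,0.16,0.0,0.0,0.0
FL21,20,21,0.0,0.06,0.01,0.03,0.08,0.01,0.0,0.02,0.0,0.01,0.04,0.05,0.0,0.03,0.01,0.0,0.05,0.0,0.05,0.01,0.0,0.21,0.03,0.0,0.0,0.04,0.01,0.0,0.23,0.02,0.0,0.0
FL22,21,22,0.0,0.03,0.02,0.03,0.07,0.0,0.0,0.01,0.0,0.01,0.03,0.03,0.0,0.04,0.0,0.0,0.01,0.0,0.11,0.03,0.0,0.16,0.05,0.0,0.0,0.01,0.05,0.0,0.3,0.01,0.0,0.0
FL23,22,23,0.0,0.0,0.01,0.03,0.06,0.0,0.0,0.03,0.01,0.0,0.02,0.0,0.01,0.03,0.0,0.0,0.0,0.03,0.28,0.07,0.0,0.03,0.0,0.0,0.01,0.01,0.05,0.01,0.28,0.0,0.0,0.0
FL24,23,24,0.0,0.01,0.0,0.04,0.04,0.0,0.0,0.01,0.01,0.02,0.05,0.01,0.0,0.05,0.01,0.0,0.0,0.04,0.18,0.13,0.0,0.05,0.0,0.0,0.01,0.03,0.03,0.01,0.28,0.0,0.0,0.0
FL25,24,25,0.0,0.0,0.0,0.02,0.05,0.01,0.0,0.05,0.01,0.01,0.03,0.0,0.0,0.03,0.01,0.0,0.0,0.01,0.23,0.11,0.0,0.03,0.05,0.0,0.01,0.0,0.05,0.01,0.31,0.0,0.0,0.0
FL26,25,26,0.0,0.02,0.0,0.05,0.05,0.01,0.0,0.01,0.0,0.0,0.03,0.0,0.0,0.04,0.0,0.0,0.0,0.01,0.17,0.15,0.01,0.03,0.01,0.0,0.01,0.02,0.09,0.02,0.25,0.01,0.0,0.0
FL27,26,27,0.0,0.07,0.03,0.07,0.04,0.01,0.0,0.01,0.0,0.01,0.05,0.01,0.0,0.03,0.0,0.0,0.0,0.01,0.17,0.11,0.01,0.03,0.04,0.0,0.0,0.0,0.02,0.02,0.26,0.0,0.0,0.0
FL28,27,28,0.0,0.08,0.06,0.01,0.07,0.01,0.0,0.01,0.01,0.03,0.05,0.01,0.0,0.01,0.01,0.01,0.0,0.01,0.13,0.14,0.01,0.02,0.02,0.0,0.0,0.01,0.04,0.01,0.23,0.01,0.0,0.0
FL29,28,29,0.01,0.06,0.02,0.02,0.07,0.01,0.0,0.03,0.0,0.01,0.0,0.03,0.0,0.02,0.02,0.0,0.0,0.0,0.27,0.11,0.0,0.02,0.03,0.0,0.0,0.02,0.06,0.0,0.19,0.0,0.0,0.0
FL30,29,30,0.01,0.09,0.02,0.01,0.05,0.0,0.0,0.03,0.0,0.05,0.03,0.0,0.0,0.01,0.01,0.0,0.0,0.01,0.24,0.09,0.0,0.01,0.02,0.0,0.0,0.05,0.02,0.0,0.26,0.01,0.0,0.0
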