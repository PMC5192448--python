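name,n_carbons,n_double_bonds,free_acid_formula,anion_formula,anion_nominal_mz,anion_monoisotopic_mz
C4:0,4,0,C4H8O2,C4H7O2-,87,87.04515
C5:0,5,0,C5H10O2,C5H9O2-,101,101.0608
C6:0,6,0,C6H12O2,C6H11O2-,115,115.07645
C7:0,7,0,C7H14O2,C7H13O2-,129,129.0921
C8:0,8,0,C8H16O2,C8H15O2-,143,143.10775
C9:0,9,0,C9H18O2,C9H17O2-,157,157.1234
C10:0,10,0,C10H20O2,C10H19O2-,171,171.13905
C11:0,11,0,C11H22O2,C11H21O2-,185,185.1547
C12:0,12,0,C12H24O2,C12H23O2-,199,199.17035
C13:0,13,0,C13H26O2,C13H25O2-,213,213.186
C14:0,14,0,C14H28O2,C14H27O2-,227,227.20165
C14:1c,14,1,C14H26O2,C14H25O2-,225,225.186
C15:0,15,0,C15H30O2,C15H29O2-,241,241.2173
C15:1c,15,1,C15H28O2,C15H27O2-,239,239.20165
C16:0,16,0,C16H32O2,C16H31O2-,255,255.23295
C16:1c,16,1,C16H30O2,C16H29O2-,253,253.2173
C17:0,17,0,C17H34O2,C17H33O2-,269,269.2486
C17:1c,17,1,C17H32O2,C17H31O2-,267,267.23295
C18:0,18,0,C18H36O2,C18H35O2-,283,283.26425
C18:1c,18,1,C18H34O2,C18H33O2-,281,281.2486
C18:1t,18,1,C18H34O2,C18H33O2-,281,281.2486
C18:2c,18,2,C18H32O2,C18H31O2-,279,279.23295
C18:2t,18,2,C18H32O2,C18H31O2-,279,279.23295
C18:3n3,18,3,C18H30O2,C18H29O2-,277,277.2173
C18:3n6,18,3,C18H30O2,C18H29O2-,277,277.2173
C19:0,19,0,C19H38O2,C19H37O2-,297,297.2799
C20:0,20,0,C20H40O2,C20H39O2-,311,311.29555
C20:1c,20,1,C20H38O2,C20H37O2-,309,309.2799
C20:2c,20,2,C20H36O2,C20H35O2-,307,307.26425
C20:3n3,20,3,C20H34O2,C20H33O2-,305,305.2486
C20:3n6,20,3,C20H34O2,C20H33O2-,305,305.2486
C20:4n6,20,4,C20H32O2,C20H31O2-,303,303.23295
C20:5n3,20,5,C20H30O2,C20H29O2-,301,301.2173
C21:0,21,0,C21H42O2,C21H41O2-,325,325.3112
C22:0,22,0,C22H44O2,C22H43O2-,339,339.32685
C22:1c,22,1,C22H42O2,C22H41O2-,337,337.3112
C22:2c,22,2,C22H40O2,C22H39O2-,335,335.29555
C22:4n6,22,4,C22H36O2,C22H35O2-,331,331.26425
C22:5n3,22,5,C22H34O2,C22H33O2-,329,329.2486
C22:6n3,22,6,C22H32O2,C22H31O2-,327,327.23295
C23:0,23,0,C23H46O2,C23H45O2-,353,353.3425
C24:0,24,0,C24H48O2,C24H47O2-,367,367.35815
C24:1c,24,1,C24H46O2,C24H45O2-,365,365.3425
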