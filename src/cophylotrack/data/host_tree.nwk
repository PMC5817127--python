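('Liriodendron tulipifera',((('Celastrus scandens',(('Cercis canadensis','Robinia pseudoacacia'),(('Juglans nigra','Juglans cinerea'),Carya))),('Dirca palustris','Ptelea trifoliata')),(('Sideroxylon lycioides','Sideroxylon lanuginosum'),((('Viburnum prunifolium','Viburnum rufidulum'),'Viburnum lentago'),'Viburnum cassinoides'))));
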